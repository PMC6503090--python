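"""Render the synoptic figures from a written analysis bundle.

Reads results/analysis/ (as produced by 03_bootstrap_inference.py) and
renders the correlation heatmap (non-significant cells crossed out), the
per-comparison ridgeline and box plots of the within-group bootstrap
distributions, and the synoptic trend table.
"""

import argparse
from pathlib import Path

from barotrend.pipeline import load_bundle
from barotrend.reporting import render_reports


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path, default=Path("results/analysis"))
    ap.add_argument("--out", type=Path, default=None)
    args = ap.parse_args()

    bundle = load_bundle(args.bundle)
    paths = render_reports(bundle, args.out or args.bundle)
    print("rendered: " + ", ".join(p.name for p in paths))


if __name__ == "__main__":
    main()
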