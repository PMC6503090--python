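"""End-to-end orchestration: adjust -> bootstrap -> infer -> classify.

``run_analysis`` executes the whole chain deterministically from one seed
and returns a :class:`ResultBundle` whose two tables mirror the study's
reporting: one row per comparison x scope (median Winsorized correlation,
BCa bounds, permutation p) and one row per comparison (HN z/p for the four
trend patterns plus the synoptic labels).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bootstrap as bt
from .adjust import adjust_cohort
from .cohort import GROUPS
from .errors import ParameterError
from .inference import (
    TREND_SCORES, HNResult, bca_interval, classify_trends, hn_trend_test,
    permutation_test_corr, strength_band,
)

log = logging.getLogger("barotrend")


@dataclass
class AnalysisConfig:
    """Tuning knobs of the full analysis; defaults are the study settings."""

    gamma: float = 0.1
    n_boot: int = 5000
    level: float = 0.95
    n_perm: int = 5000
    seed: int = 0
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.gamma < 0.5:
            raise ParameterError("gamma must be in [0, 0.5)")
        if self.n_boot < 1 or self.n_perm < 1:
            raise ParameterError("n_boot and n_perm must be >= 1")
        if not 0 < self.level < 1:
            raise ParameterError("level must be in (0, 1)")


@dataclass
class ResultBundle:
    summary: pd.DataFrame          # comparison x scope rows
    trends: pd.DataFrame           # one row per comparison
    ensemble: bt.BootstrapEnsemble
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "summary": out / "correlation_summary.csv",
            "trends": out / "trend_results.csv",
            "manifest": out / "manifest.json",
        }
        self.summary.to_csv(paths["summary"], index=False)
        self.trends.to_csv(paths["trends"], index=False)
        paths["manifest"].write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True) + "\n"
        )
        for scope_i, scope in enumerate(self.ensemble.scopes):
            p = out / f"ensemble_{scope}.csv"
            pd.DataFrame(
                self.ensemble.values[:, :, scope_i],
                columns=list(self.ensemble.comparisons),
            ).to_csv(p, index=False)
            paths[f"ensemble_{scope}"] = p
        return paths


def load_bundle(bundle_dir) -> ResultBundle:
    """Reconstruct a ResultBundle from a directory written by ``write``."""
    bundle_dir = Path(bundle_dir)
    summary = pd.read_csv(bundle_dir / "correlation_summary.csv")
    trends = pd.read_csv(bundle_dir / "trend_results.csv")
    manifest = json.loads((bundle_dir / "manifest.json").read_text())
    vals = np.stack(
        [
            pd.read_csv(bundle_dir / f"ensemble_{scope}.csv").to_numpy()
            for scope in bt.SCOPES
        ],
        axis=2,
    )
    ensemble = bt.BootstrapEnsemble(
        values=vals, gamma=manifest["gamma"], seed=manifest["seed"], B=manifest["B"]
    )
    return ResultBundle(
        summary=summary, trends=trends, ensemble=ensemble, provenance=manifest
    )


def run_analysis(config: AnalysisConfig, cohort: pd.DataFrame) -> ResultBundle:
    """Run the full chain on one cohort; deterministic given ``config.seed``."""
    adjusted = adjust_cohort(cohort)

    log.info("stage=plan B=%d strata=%d", config.n_boot, cohort["stratum"].nunique())
    plan = bt.balanced_stratified_plan(
        cohort["stratum"].to_numpy(), config.n_boot, config.seed
    )
    log.info("stage=ensemble gamma=%.3f", config.gamma)
    ensemble = bt.bootstrap_wincorr_ensemble(cohort, plan, config.gamma)
    flagged = int(ensemble.n_flagged.sum())
    log.info("stage=ensemble done flagged_cells=%d", flagged)

    medians = bt.ensemble_median(ensemble)
    observed = bt.observed_wincorr(cohort, config.gamma)
    log.info("stage=jackknife n=%d", len(cohort))
    jack = bt.jackknife_wincorr(cohort, config.gamma)

    x = adjusted["alpha_adj"].to_numpy()
    y_cols = [
        f"{c}_adj" if c != "ansi" else "ansi" for c in ensemble.comparisons
    ]
    group_arr = adjusted["group"].to_numpy()

    rows = []
    perm_sig = np.zeros((len(ensemble.comparisons), len(GROUPS)), dtype=bool)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(10,)))
    for ci, comp in enumerate(ensemble.comparisons):
        y = adjusted[y_cols[ci]].to_numpy()
        for si, scope in enumerate(ensemble.scopes):
            mask = np.ones(len(x), bool) if scope == "overall" else group_arr == scope
            try:
                perm = permutation_test_corr(
                    x[mask], y[mask], config.gamma, config.n_perm,
                    seed=rng.integers(2**31),
                )
                p_val, t_obs = perm.p_value, perm.observed
            except Exception as exc:
                raise RuntimeError(
                    f"permutation test failed at {comp}/{scope}: {exc}"
                ) from exc
            if scope != "overall":
                perm_sig[ci, si - 1] = p_val < 0.05
            try:
                ci_ = bca_interval(
                    float(observed[ci, si]), ensemble.values[:, ci, si],
                    jack[:, ci, si], config.level,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"BCa interval failed at {comp}/{scope}: {exc}"
                ) from exc
            rows.append(
                {
                    "comparison": comp, "scope": scope,
                    "median_wincorr": medians[ci, si],
                    "observed_wincorr": float(observed[ci, si]),
                    "bca_lower": ci_.lower, "bca_upper": ci_.upper,
                    "perm_p": p_val, "perm_observed": t_obs,
                    "band": strength_band(medians[ci, si]),
                    "n_flagged": int(ensemble.n_flagged[ci, si]),
                }
            )
    summary = pd.DataFrame(rows)

    # HN tests on the three within-group bootstrap distributions (equal n = B)
    hn: dict[str, list[HNResult]] = {name: [] for name in TREND_SCORES}
    for ci in range(len(ensemble.comparisons)):
        samples = [ensemble.values[:, ci, 1 + gi] for gi in range(len(GROUPS))]
        samples = [s[np.isfinite(s)] for s in samples]
        for name, scores in TREND_SCORES.items():
            hn[name].append(hn_trend_test(samples, scores))
    group_medians = medians[:, 1:]
    trends = classify_trends(
        group_medians, perm_sig, hn, list(ensemble.comparisons)
    )
    trend_rows = []
    for ci, tr in enumerate(trends):
        row = {
            "comparison": tr.comparison,
            "monotonic": tr.monotonic, "monotonic_p": tr.monotonic_p,
            "umbrella": tr.umbrella, "umbrella_p": tr.umbrella_p,
            "endpoint_profile": tr.endpoint_profile,
            "strongest_group": tr.strongest,
            "strongest_median": tr.strongest_median, "band": tr.band,
        }
        for name in TREND_SCORES:
            row[f"hn_z_{name}"] = hn[name][ci].z
            row[f"hn_p_{name}"] = hn[name][ci].p_value
        trend_rows.append(row)
    trends_df = pd.DataFrame(trend_rows)
    n_sig = int((summary.loc[summary.scope == "overall", "perm_p"] < 0.05).sum())
    trends_df["n_significant_overall"] = n_sig

    bundle = ResultBundle(
        summary=summary,
        trends=trends_df,
        ensemble=ensemble,
        provenance={
            "seed": int(config.seed), "B": int(config.n_boot),
            "gamma": config.gamma, "level": config.level,
            "n_perm": int(config.n_perm), "n_subjects": int(len(cohort)),
            "flagged_cells": flagged,
        },
    )
    if config.out_dir is not None:
        bundle.write(config.out_dir)
    return bundle
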