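"""YAML/JSON (de)serialisation of designs, effects and calibrations."""

from __future__ import annotations

from pathlib import Path

import yaml

from .cohort import CohortDesign, CorrelationCalibration, FactorEffects


def load_design(path) -> CohortDesign:
    return CohortDesign.from_dict(yaml.safe_load(Path(path).read_text()))


def save_design(design: CohortDesign, path) -> None:
    Path(path).write_text(yaml.safe_dump(design.to_dict(), sort_keys=False))


def load_effects(path) -> FactorEffects:
    return FactorEffects.from_dict(yaml.safe_load(Path(path).read_text()))


def save_effects(effects: FactorEffects, path) -> None:
    Path(path).write_text(yaml.safe_dump(effects.to_dict(), sort_keys=False))


def load_calibration(path) -> CorrelationCalibration:
    return CorrelationCalibration.from_dict(yaml.safe_load(Path(path).read_text()))


def save_calibration(calib: CorrelationCalibration, path) -> None:
    Path(path).write_text(yaml.safe_dump(calib.to_dict(), sort_keys=False))
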