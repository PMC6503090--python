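import numpy as np
import pytest

from barotrend.cohort import (
    CohortDesign, CorrelationCalibration, FactorEffects, Stratum,
    default_calibration, default_design, generate_cohort,
)


@pytest.fixture(scope="session")
def small_design() -> CohortDesign:
    """A miniature 100-subject design with one stratum per SAP group."""
    strata = (
        Stratum("Nt", 100, 130, False, 40, "Nt"),
        Stratum("preHt", 130, 140, False, 30, "preHt"),
        Stratum("Ht", 140, 200, True, 30, "Ht"),
    )
    cells = {}
    for group, total in (("Nt", 40), ("preHt", 30), ("Ht", 30)):
        per = total // 6
        rem = total - 5 * per
        counts = [per] * 5 + [rem]
        k = 0
        for g in ("F", "M"):
            for a in ("17-30", "31-49", "50-86"):
                cells[(g, a, group)] = counts[k]
                k += 1
    return CohortDesign(strata=strata, cell_counts=cells)


@pytest.fixture(scope="session")
def flat_calibration() -> CorrelationCalibration:
    """The same medium loading for every proxy in every group."""
    return CorrelationCalibration(
        loadings={"overall": {p: 0.5 for p in (
            "hr", "rr_mean", "rr_tp", "rr_lfa", "rr_hfa", "rr_lfnu", "rr_hfnu",
            "rr_lfhf", "d_rr_lfnu", "sap_v", "dap", "sap_mean", "sap_lfa",
        )}}
    )


@pytest.fixture(scope="session")
def small_cohort(small_design, flat_calibration):
    """Clean (uncontaminated) miniature cohort with default demographic biases."""
    return generate_cohort(
        small_design, FactorEffects.default(), flat_calibration,
        contamination_fraction=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def paper_cohort():
    """One full-scale cohort from the study design and calibration."""
    return generate_cohort(
        default_design(), FactorEffects.default(), default_calibration(),
        contamination_fraction=0.01, seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
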