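"""Age/gender adjustment of the ANS variables and the ANSI composite.

Every variable (the baroreflex ``alpha`` index and the 13 ANS proxies) is
replaced by its residual from a saturated two-way ANOVA on gender and
age-class (main effects plus interaction).  Because the model is saturated,
the fitted value of a subject is exactly its (gender, age-class) cell mean,
so the residual is the deviation from the cell mean — no design matrix or
matrix inversion is needed, and the residuals are exactly orthogonal to
every cell indicator.

ANSI (Autonomic Nervous System Index) is a unitary 0-100 composite built
from RR Mean, RR variance and the stand-rest shift of normalized LF power:
each component is cell-means adjusted, converted to a percent rank (midrank
convention), the three percent ranks are averaged with equal weights, and
the average is re-expressed as a percent rank.  The rank-based construction
makes ANSI invariant to monotone re-expressions of its components and, by
design, free of the age and gender biases the adjustment removes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import ANSI_COMPONENTS, GENDERS, AGE_CLASSES, VARIABLES
from .errors import DegenerateInputError, MissingCellError

#: fixed cell order used by the vectorized kernels
CELLS = [(g, a) for g in GENDERS for a in AGE_CLASSES]
_CELL_INDEX = {c: i for i, c in enumerate(CELLS)}


def cell_codes(gender, age_class) -> np.ndarray:
    """Integer code of each subject's (gender, age-class) cell."""
    try:
        return np.array(
            [_CELL_INDEX[(g, a)] for g, a in zip(gender, age_class)], dtype=np.intp
        )
    except KeyError as exc:  # pragma: no cover - defensive
        raise MissingCellError(f"undefined cell {exc.args[0]!r}") from exc


def cell_residuals(values: np.ndarray, codes: np.ndarray, n_cells: int = len(CELLS)):
    """Residuals from cell means, vectorized over columns.

    ``values`` is (n,) or (n, k); returns residuals of the same shape plus
    the (n_cells, k) matrix of cell means (NaN for empty cells).
    """
    v = np.asarray(values, dtype=float)
    one_d = v.ndim == 1
    if one_d:
        v = v[:, None]
    counts = np.bincount(codes, minlength=n_cells).astype(float)
    sums = np.zeros((n_cells, v.shape[1]))
    np.add.at(sums, codes, v)
    with np.errstate(invalid="ignore"):
        means = sums / counts[:, None]
    resid = v - means[codes]
    if one_d:
        return resid[:, 0], means[:, 0]
    return resid, means


@dataclass(frozen=True)
class CellMeansModel:
    """Fitted saturated two-way model: one mean per non-empty cell."""

    cell_means: Mapping[tuple[str, str], float]
    grand_mean: float

    def predict(self, gender, age_class) -> np.ndarray:
        out = np.empty(len(gender))
        for i, cell in enumerate(zip(gender, age_class)):
            if cell not in self.cell_means:
                raise MissingCellError(f"no fitted mean for cell {cell!r}")
            out[i] = self.cell_means[cell]
        return out

    def residuals(self, values, gender, age_class) -> np.ndarray:
        return np.asarray(values, dtype=float) - self.predict(gender, age_class)


def fit_cell_means(values, gender, age_class) -> CellMeansModel:
    """Fit the saturated gender x age-class model to one variable."""
    v = np.asarray(values, dtype=float)
    if not (len(v) == len(gender) == len(age_class)):
        raise ValueError("inputs must have equal length")
    codes = cell_codes(gender, age_class)
    _, means = cell_residuals(v, codes)
    fitted = {
        cell: float(means[i]) for cell, i in _CELL_INDEX.items()
        if np.isfinite(means[i])
    }
    return CellMeansModel(cell_means=fitted, grand_mean=float(v.mean()))


def percent_rank(x) -> np.ndarray:
    """Midrank percent ranks on a 0-100 scale; a full tie maps to 50."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise DegenerateInputError("percent rank undefined for n < 2")
    return (rankdata(x, method="average") - 0.5) / n * 100.0


def compute_ansi(cohort: pd.DataFrame) -> np.ndarray:
    """ANSI percent ranks (0-100) from the three HRV components."""
    codes = cell_codes(cohort["gender"], cohort["age_class"])
    comp_ranks = []
    for comp in ANSI_COMPONENTS:
        resid, _ = cell_residuals(cohort[comp].to_numpy(), codes)
        comp_ranks.append(percent_rank(resid))
    return percent_rank(np.mean(comp_ranks, axis=0))


def adjust_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Replace alpha and the 13 proxies by adjusted values; append ANSI.

    Returns a frame with ``<var>_adj`` columns (ANOVA residuals in the
    variable's units), the ``ansi`` column, and the carried-over subject,
    stratum and group labels.
    """
    codes = cell_codes(cohort["gender"], cohort["age_class"])
    v = cohort[list(VARIABLES)].to_numpy(dtype=float)
    resid, _ = cell_residuals(v, codes)
    out = cohort[
        ["subject_id", "age", "gender", "age_class", "sap_clinic", "stratum", "group"]
    ].copy()
    for j, var in enumerate(VARIABLES):
        out[f"{var}_adj"] = resid[:, j]
    out["ansi"] = compute_ansi(cohort)
    return out
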