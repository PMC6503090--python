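"""Stratified balanced bootstrap of the Winsorized correlation landscape.

The resampling scheme reproduces two properties simultaneously:

* **stratification** — every replicate contains exactly the original number
  of subjects of each SAP stratum (hence also of each SAP group, groups
  being unions of strata);
* **balance** — across the whole ensemble of B replicates each subject is
  drawn exactly B times in total, which reduces bootstrap simulation error
  relative to ordinary independent resampling.

Both are achieved per stratum by concatenating B copies of the stratum's
subject indices, applying one uniform permutation, and slicing the result
into B consecutive blocks: block b is replicate b's draw for that stratum.

On every replicate the age/gender adjustment and ANSI are *recomputed from
scratch* on the resampled subjects, and the gamma-Winsorized correlation of
adjusted alpha with each of the 13 adjusted proxies plus ANSI is evaluated
overall and within the three SAP groups, yielding a (B, 14, 4) ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .adjust import cell_codes, cell_residuals, percent_rank
from .cohort import GROUPS, PROXIES, VARIABLES
from .errors import ConfigurationError, DegenerateInputError
from .robust import _check_gamma, winsorize

#: comparison labels: adjusted alpha against each of these
COMPARISONS = tuple(PROXIES) + ("ansi",)
#: correlation scopes: the whole cohort plus the three SAP groups
SCOPES = ("overall",) + GROUPS


@dataclass(frozen=True)
class BootstrapPlan:
    """Replicate-by-subject index matrix of a stratified balanced bootstrap.

    ``indices[b]`` lists the subject rows of replicate ``b`` (stratum blocks
    concatenated in stratum order).  Within each stratum every subject index
    appears exactly B times across the whole matrix.
    """

    indices: np.ndarray  # (B, n) intp
    stratum_labels: tuple[str, ...]
    seed: int
    B: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "B", int(self.indices.shape[0]))


def balanced_stratified_plan(stratum_labels, B: int, seed: int) -> BootstrapPlan:
    """Permute-B-copies-and-slice balanced bootstrap within each stratum."""
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    labels = np.asarray(stratum_labels)
    if len(labels) == 0:
        raise ConfigurationError("empty cohort")
    rng = np.random.default_rng(seed)
    blocks = []
    uniq = list(pd.unique(labels))
    for lab in uniq:
        idx = np.flatnonzero(labels == lab)
        if idx.size == 0:  # pragma: no cover - unreachable with pd.unique
            raise ConfigurationError(f"empty stratum {lab!r}")
        tiled = np.tile(idx, B)
        perm = rng.permutation(tiled.size)
        blocks.append(tiled[perm].reshape(B, idx.size))
    indices = np.concatenate(blocks, axis=1)
    return BootstrapPlan(indices=indices, stratum_labels=tuple(uniq), seed=int(seed))


@dataclass(frozen=True)
class BootstrapEnsemble:
    """(B, comparison, scope) array of Winsorized correlations.

    Degenerate cells (zero winsorized variance inside a replicate scope)
    are NaN; ``n_flagged`` counts them per (comparison, scope).
    """

    values: np.ndarray  # (B, 14, 4), NaN where degenerate
    gamma: float
    seed: int
    B: int
    comparisons: tuple[str, ...] = COMPARISONS
    scopes: tuple[str, ...] = SCOPES

    @property
    def n_flagged(self) -> np.ndarray:
        return np.isnan(self.values).sum(axis=0)


def _wincorr_block(x: np.ndarray, ys: np.ndarray, gamma: float) -> np.ndarray:
    """gamma-Winsorized correlation of x against each column of ys.

    Returns NaN (not an error) for degenerate columns; the caller flags
    them.  Winsorizing is a pointwise clamp at overall order statistics, so
    it is computed once per vector.
    """
    n = x.shape[0]
    out = np.full(ys.shape[1], np.nan)
    if n < 3:
        return out
    xw = winsorize(x, gamma)
    xc = xw - xw.mean()
    sx = float(xc @ xc)
    if sx == 0.0:
        return out
    for j in range(ys.shape[1]):
        yw = winsorize(ys[:, j], gamma)
        yc = yw - yw.mean()
        sy = float(yc @ yc)
        if sy == 0.0:
            continue
        out[j] = np.clip((xc @ yc) / np.sqrt(sx * sy), -1.0, 1.0)
    return out


def _replicate_wincorr(
    V: np.ndarray, codes: np.ndarray, group_codes: np.ndarray, gamma: float
) -> np.ndarray:
    """Adjust, compute ANSI and all (comparison, scope) WINcorr on one sample.

    ``V`` holds the *raw* variables (columns in VARIABLES order) of the
    (re)sampled subjects; adjustment and ANSI are refit on this sample.
    """
    resid, _ = cell_residuals(V, codes)
    comp_idx = [VARIABLES.index(c) for c in ("rr_mean", "rr_tp", "d_rr_lfnu")]
    comp_ranks = (rankdata(resid[:, comp_idx], method="average", axis=0) - 0.5) / len(
        resid
    ) * 100.0
    ansi = percent_rank(comp_ranks.mean(axis=1))
    x = resid[:, 0]
    ys = np.column_stack([resid[:, 1:], ansi])
    out = np.empty((len(COMPARISONS), len(SCOPES)))
    out[:, 0] = _wincorr_block(x, ys, gamma)
    for gi in range(len(GROUPS)):
        mask = group_codes == gi
        out[:, gi + 1] = _wincorr_block(x[mask], ys[mask], gamma)
    return out


def _cohort_arrays(cohort: pd.DataFrame):
    V = cohort[list(VARIABLES)].to_numpy(dtype=float)
    codes = cell_codes(cohort["gender"], cohort["age_class"])
    group_codes = np.array([GROUPS.index(g) for g in cohort["group"]], dtype=np.intp)
    return V, codes, group_codes


def observed_wincorr(cohort: pd.DataFrame, gamma: float = 0.1) -> np.ndarray:
    """The (14, 4) WINcorr matrix of the original cohort (adjusted in full)."""
    _check_gamma(gamma)
    V, codes, group_codes = _cohort_arrays(cohort)
    return _replicate_wincorr(V, codes, group_codes, gamma)


def bootstrap_wincorr_ensemble(
    cohort: pd.DataFrame, plan: BootstrapPlan, gamma: float = 0.1
) -> BootstrapEnsemble:
    """Recompute adjustment, ANSI and WINcorr on every planned replicate."""
    _check_gamma(gamma)
    V, codes, group_codes = _cohort_arrays(cohort)
    if plan.indices.shape[1] != len(cohort):
        raise ConfigurationError("plan was built for a different cohort size")
    B = plan.B
    values = np.empty((B, len(COMPARISONS), len(SCOPES)))
    for b in range(B):
        rows = plan.indices[b]
        values[b] = _replicate_wincorr(
            V[rows], codes[rows], group_codes[rows], gamma
        )
    return BootstrapEnsemble(
        values=values, gamma=float(gamma), seed=plan.seed, B=B
    )


def jackknife_wincorr(cohort: pd.DataFrame, gamma: float = 0.1) -> np.ndarray:
    """Delete-one (n, 14, 4) WINcorr values with full per-deletion refit.

    Used for the acceleration constant of the BCa intervals; each deletion
    re-runs the adjustment and ANSI exactly like a bootstrap replicate.
    """
    _check_gamma(gamma)
    V, codes, group_codes = _cohort_arrays(cohort)
    n = len(cohort)
    out = np.empty((n, len(COMPARISONS), len(SCOPES)))
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        out[i] = _replicate_wincorr(
            V[keep], codes[keep], group_codes[keep], gamma
        )
        keep[i] = True
    return out


def ensemble_median(ensemble: BootstrapEnsemble) -> np.ndarray:
    """Componentwise median over replicates (midpoint for even counts)."""
    vals = ensemble.values
    if np.isnan(vals).all(axis=0).any():
        raise DegenerateInputError("a (comparison, scope) cell has no valid replicate")
    return np.nanmedian(vals, axis=0)


def median_frame(ensemble: BootstrapEnsemble) -> pd.DataFrame:
    med = ensemble_median(ensemble)
    return pd.DataFrame(med, index=list(ensemble.comparisons), columns=list(ensemble.scopes))
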