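"""Non-parametric inference on the bootstrap correlation landscape.

Four ingredients:

* **BCa intervals** — bias-corrected and accelerated bootstrap percentile
  intervals.  The bias correction ``z0`` is the normal quantile of the
  fraction of bootstrap values below the original-data statistic; the
  acceleration ``a`` is the standardized skewness of the delete-one
  jackknife values; the interval endpoints are adjusted percentiles of the
  bootstrap distribution.
* **Permutation test of zero correlation** — the Winsorized correlation is
  recomputed under uniform permutations of one variable (exchangeable under
  the null of no association); the two-sided p-value uses the add-one rule
  ``p = (1 + #{|T*| >= |T|}) / (n_perm + 1)``.
* **Hettmansperger–Norton patterned-trend test** — a linear rank statistic
  against an *ordered* alternative over the three SAP groups, either
  monotonic (scores 1,2,3 or 3,2,1) or umbrella-shaped (concave 1,2,1 /
  convex 2,1,2).  It is less sensitive to variance heterogeneity than the
  Jonckheere–Terpstra or Mack–Wolfe tests, which motivates its use on
  bootstrap correlation distributions.
* **Trend classification** — the synoptic per-comparison labelling:
  monotonic direction, umbrella shape, and the SAP group with the strongest
  (absolute) median correlation, banded by strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

from .cohort import GROUPS
from .errors import DegenerateInputError, ParameterError
from .robust import _check_gamma, winsorize

#: canonical score vectors over the ordered groups (Nt, preHt, Ht)
TREND_SCORES: dict[str, tuple[int, int, int]] = {
    "increasing": (1, 2, 3),
    "decreasing": (3, 2, 1),
    "concave": (1, 2, 1),
    "convex": (2, 1, 2),
}

#: absolute-correlation strength bands for the synoptic report
STRENGTH_BANDS = (
    (0.2, "negligible"),
    (0.4, "weak"),
    (0.6, "medium"),
    (np.inf, "strong"),
)


def strength_band(r: float) -> str:
    for bound, label in STRENGTH_BANDS:
        if abs(r) < bound:
            return label
    return "strong"  # pragma: no cover


@dataclass(frozen=True)
class BcaInterval:
    lower: float
    upper: float
    level: float
    z0: float
    a: float
    flagged: bool = False


def bca_interval(theta_hat: float, boot_values, jackknife_values, level: float = 0.95) -> BcaInterval:
    """BCa confidence interval from bootstrap and jackknife values.

    ``theta_hat`` is the statistic on the original data (the interval's
    reference point).  Counts defining ``z0`` are clamped to [1, B-1] so the
    normal quantile stays finite; an interval needing that clamp is
    returned ``flagged`` rather than rejected.
    """
    boot = np.asarray(boot_values, dtype=float)
    boot = boot[np.isfinite(boot)]
    jack = np.asarray(jackknife_values, dtype=float)
    B = boot.size
    if B < 100:
        raise ParameterError("need at least 100 bootstrap values")
    if jack.size < 3:
        raise ParameterError("need at least 3 jackknife values")
    if not 0 < level < 1:
        raise ParameterError("level must be in (0, 1)")
    if np.ptp(boot) == 0.0:
        raise DegenerateInputError("constant bootstrap distribution")

    count = int(np.sum(boot < theta_hat))
    flagged = count < 1 or count > B - 1
    count = min(max(count, 1), B - 1)
    z0 = ndtri(count / B)

    d = jack.mean() - jack
    denom = float(np.sum(d * d)) ** 1.5
    a = float(np.sum(d**3) / (6.0 * denom)) if denom > 0 else 0.0

    z_lo = ndtri((1.0 - level) / 2.0)
    z_hi = -z_lo
    lims = []
    for z in (z_lo, z_hi):
        adj = z0 + (z0 + z) / (1.0 - a * (z0 + z))
        lims.append(float(np.quantile(boot, np.clip(ndtr(adj), 0.0, 1.0))))
    return BcaInterval(
        lower=min(lims), upper=max(lims), level=level, z0=float(z0), a=a,
        flagged=flagged,
    )


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    p_value: float
    n_perm: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def permutation_test_corr(x, y, gamma: float = 0.1, n_perm: int = 5000, seed=0) -> PermutationResult:
    """Two-sided permutation test of zero Winsorized correlation.

    Winsorization commutes with permutation (it is a pointwise clamp at
    overall order statistics), so both vectors are winsorized once and only
    the cross products are recomputed per permutation.
    """
    _check_gamma(gamma)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    xw = winsorize(x, gamma)
    yw = winsorize(y, gamma)
    xc = xw - xw.mean()
    yc = yw - yw.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("zero winsorized variance")
    norm = math.sqrt(sx * sy)
    t_obs = float(xc @ yc) / norm

    n = len(x)
    # permute in manageable chunks to bound memory at large n_perm
    exceed = 0
    chunk = max(1, int(2_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        order = np.argsort(rng.random((m, n)), axis=1)
        t_perm = (yc[order] @ xc) / norm
        exceed += int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12))
        done += m
    p = (1.0 + exceed) / (n_perm + 1.0)
    return PermutationResult(observed=t_obs, p_value=float(p), n_perm=int(n_perm))


@dataclass(frozen=True)
class HNResult:
    z: float
    p_value: float
    scores: tuple[int, ...]

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def hn_trend_test(samples: Sequence, scores: Sequence[float]) -> HNResult:
    """Hettmansperger–Norton rank test against one patterned alternative.

    Pools all N values, assigns midranks, centres the scores ``q_i`` by the
    size-weighted mean and forms the linear rank statistic
    ``T = sum_i n_i c_i Rbar_i`` with exact permutation variance
    ``sigma_R^2 * N/(N-1) * sum_i n_i c_i^2`` (``sigma_R^2`` the population
    variance of the pooled midranks).  With equal group sizes — the only
    case the pipeline uses, its inputs being three bootstrap distributions
    of size B — pseudoranks coincide with plain midranks and this reduces
    to the familiar equal-n standardization.  One-sided upper-tail p.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    scores = np.asarray(scores, dtype=float)
    if len(samples) != len(scores):
        raise ValueError("one score per group required")
    if np.ptp(scores) == 0:
        raise ParameterError("scores must not be constant")
    sizes = np.array([s.size for s in samples])
    if np.any(sizes < 2):
        raise ValueError("each sample needs n >= 2")
    pooled = np.concatenate(samples)
    N = pooled.size
    ranks = rankdata(pooled, method="average")
    sigma2 = float(np.var(ranks))  # population variance of the midranks
    if sigma2 == 0.0:
        raise DegenerateInputError("all pooled values tied")
    c = scores - float(sizes @ scores) / N
    w = sizes * c  # weighted contrast: sums to zero by construction
    means = []
    start = 0
    for m in sizes:
        means.append(ranks[start:start + m].mean())
        start += m
    T = float(w @ np.asarray(means))
    var = sigma2 * N / (N - 1.0) * float(np.sum(w * w / sizes))
    z = T / math.sqrt(var)
    return HNResult(z=float(z), p_value=float(1.0 - ndtr(z)), scores=tuple(scores))


@dataclass(frozen=True)
class TrendResult:
    """Synoptic classification of one alpha-vs-proxy comparison."""

    comparison: str
    monotonic: str          # increasing / decreasing / none
    monotonic_p: float
    umbrella: str           # concave / convex / none
    umbrella_p: float
    endpoint_profile: str   # e.g. "neg -> ~0" from permutation verdicts
    strongest: str          # Nt / preHt / Ht / tie
    strongest_median: float
    band: str


def _endpoint_label(median: float, significant: bool) -> str:
    if not significant:
        return "~0"
    return "pos" if median > 0 else "neg"


def classify_trends(
    medians: np.ndarray,
    perm_significant: np.ndarray,
    hn: Mapping[str, Sequence[HNResult]],
    comparisons: Sequence[str],
    alpha_level: float = 0.05,
) -> list[TrendResult]:
    """Combine medians, permutation verdicts and HN tests per comparison.

    ``medians`` is (n_comparisons, 3) over the ordered groups;
    ``perm_significant`` is a boolean (n_comparisons, 3) of within-group
    permutation verdicts; ``hn`` maps each pattern name to the per-
    comparison HN results.  Exactly equal strongest |medians| are reported
    as a tie, never silently broken.
    """
    results = []
    for i, comp in enumerate(comparisons):
        row = medians[i]
        inc, dec = hn["increasing"][i], hn["decreasing"][i]
        mono, mono_p = "none", min(inc.p_value, dec.p_value)
        if inc.p_value < alpha_level or dec.p_value < alpha_level:
            mono = "increasing" if inc.p_value <= dec.p_value else "decreasing"
        con, vex = hn["concave"][i], hn["convex"][i]
        umb, umb_p = "none", min(con.p_value, vex.p_value)
        if con.p_value < alpha_level or vex.p_value < alpha_level:
            umb = "concave" if con.p_value <= vex.p_value else "convex"
        profile = "{} -> {}".format(
            _endpoint_label(row[0], bool(perm_significant[i, 0])),
            _endpoint_label(row[-1], bool(perm_significant[i, -1])),
        )
        best = np.abs(row).max()
        winner_idx = [j for j in range(len(GROUPS)) if abs(row[j]) == best]
        strongest = GROUPS[winner_idx[0]] if len(winner_idx) == 1 else "tie"
        best = float(row[winner_idx[0]])  # signed median of the winning group
        results.append(
            TrendResult(
                comparison=comp, monotonic=mono, monotonic_p=mono_p,
                umbrella=umb, umbrella_p=umb_p, endpoint_profile=profile,
                strongest=strongest, strongest_median=float(best),
                band=strength_band(best),
            )
        )
    return results
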