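# Methods

## Cohort model

The generator emulates a cross-sectional cohort of 1154 untreated adult
subjects whose clinic SAP defines three groups — Nt (< 130 mmHg, n = 778),
preHt ([130, 140), n = 144), Ht (≥ 140, n = 232) — refined into seven SAP
strata ([80,100) 84, [100,110) 158, [110,120) 282, [120,130) 254, [130,140)
144, [140,160) 167, [160,220] 65). The gender × age-class × group cell
counts reproduce the study composition (646 F / 508 M; age classes 17–30,
31–49, 50–86). Counts are matched *exactly*, every seed: subjects are
instantiated per cell and strata are assigned within each group by a
random permutation of the exact stratum multiset. Clinic SAP is uniform
within the stratum interval (the last stratum is closed above, the others
half-open); age is an integer uniform on its class.

Within each SAP group the standardized α index and the 13 proxies follow a
single-factor Gaussian model

    proxy_i = L_i α + sqrt(1 − L_i²) ε_i ,   ε_i ~ N(0,1) iid,

so corr(α, proxy_i) = L_i and corr(proxy_i, proxy_j) = L_i·L_j. The factor
construction was chosen because the study reports only α-vs-proxy
correlations; it yields a valid (positive-definite) joint matrix for any
loadings without specifying the unreported proxy–proxy structure. Scores
are mapped to physiological units by per-variable location/scale
placeholders (e.g. α 12 ± 6 ms/mmHg, RR mean 850 ± 120 ms) — the study's
descriptive moments are not transcribed, so these are plausible resting
values for healthy adults, fully configurable and irrelevant to every
correlation- and rank-based statistic downstream.

**Demographic effects.** Additive (gender, age-class) shifts, expressed in
SD units of each variable (defaults: HRV indices and α decline with age,
pressure indices rise, LF-balance indices shift with gender), emulate the
biases the adjustment stage must remove. Because the shifts are additive
and cell-aligned, the adjusted variables recover the configured
within-group correlations.

**ANSI calibration.** ANSI is *computed*, not generated: percent rank of
the mean of the three components' percent ranks (components cell-means
adjusted first). A per-group α–ANSI target r therefore determines the
three component loadings rather than being a free parameter. A common
loading ℓ is found by Brent root-finding on a fixed 200 000-draw Monte
Carlo of the exact rank chain (the double rank transform attenuates the
correlation; e.g. target 0.618 → ℓ ≈ 0.431); when a target is set it
overrides any directly specified loadings for those three components. The
attainable range is |r| ≲ 0.977 (the normal-score/rank correlation bound).
The default calibration uses the published per-group α–ANSI values
(0.5 / 0.618 / 0.444) and published per-group α–RR LFnu values, with the
remaining loadings fixed at medium magnitudes mirroring the study's
qualitative umbrella patterns. Note that per-group calibration determines
the whole-cohort correlation as a count-weighted mixture (≈ 0.50 for
α–ANSI); whole-cohort published values can instead be targeted directly by
putting the loading in the `overall` scope.

**Contamination.** A fraction (default 1%) of subjects receives ± 6 SD
displacements on a random ~half of the proxies, mimicking subjects with
outlying values on several but not all measures — the rationale for the
Winsorized correlation. Demographics, factor scores and contamination use
independent named substreams of one master seed.

## Adjustment

The "two-way full ANOVA" residual is computed as deviation from the
(gender × age-class) cell mean — identical to the saturated linear model's
residual but exact and inversion-free. Residuals are exactly orthogonal to
every cell indicator; adjustment is idempotent. ANSI uses midranks
throughout, on the (rank − 0.5)/n × 100 scale, so a fully tied input maps
to 50 and the output lies strictly inside (0, 100).

## Winsorized correlation

g = ⌊γn⌋ per tail; the g smallest values are replaced by the (g+1)-th order
statistic and the g largest by the (n−g)-th (implemented as a clip, which
is equivalent and order-preserving); Pearson's formula is applied to the
two independently clamped vectors. γ = 0.1 is the study default; γ = 0
reduces exactly to Pearson. Zero winsorized variance raises a
degenerate-input error rather than returning 0 (inside the bootstrap such
cells are flagged NaN, logged and excluded from aggregation).

## Bootstrap

Per stratum of size m: concatenate B copies of the stratum's indices,
permute the mB entries once, slice into B blocks of m. This realizes exact
per-replicate stratum counts and exact total multiplicity B per subject
simultaneously. Group membership travels with the resampled subjects;
since groups are unions of strata, group counts are also exact. On each
replicate the cell-means adjustment and ANSI (including its percentile
reference) are recomputed from the replicate's own data before the 14 × 4
WINcorr evaluations; the ensemble is summarized by componentwise medians
(midpoint convention). The per-replicate kernel is vectorized
(bincount-based cell means, one rank pass for ANSI, clip-based
winsorization), ≈ 2.4 ms at n = 1154, so the study-scale B = 5000 ensemble
takes ≈ 12 s on one CPU.

## Inference

**BCa.** z₀ = Φ⁻¹(#{boot < θ̂}/B) with counts clamped to [1, B−1] (a clamp
flags the interval); a = Σ(m−jᵢ)³ / (6[Σ(m−jᵢ)²]^{3/2}) from delete-one
jackknife values computed with the same full per-deletion refit as a
bootstrap replicate; endpoints are linear-interpolated quantiles of the
bootstrap distribution at the adjusted percentiles. θ̂ is the original-data
WINcorr (the bootstrap median is an alternative reference; the observed
statistic is the conventional BCa choice and is reported alongside).

**Permutation test.** H₀: ρ = 0 is tested by permuting the second variable
uniformly (within the scope's group for group scopes), two-sided p =
(1 + #{|T*| ≥ |T|})/(n_perm + 1). Winsorization commutes with permutation
(it is a pointwise clamp at whole-sample order statistics), so both
vectors are winsorized once and only cross-products are recomputed.

**Hettmansperger–Norton test.** For ordered samples with scores q_i, pool
all N values, midrank them, centre the scores by the size-weighted mean
(c_i = q_i − Σn_j q_j/N) and form T = Σ n_i c_i R̄_i with permutation
variance σ_R² · N/(N−1) · Σ n_i c_i², σ_R² the population variance of the
pooled midranks; z = T/√Var, upper-tail normal p. The weighted centring
gives T exact zero permutation mean for *any* group sizes; with equal
sizes (the pipeline's case — three bootstrap distributions of size B,
where pseudoranks coincide with plain ranks) it reduces to the familiar
equal-n standardization, verified against full enumeration of the
permutation null on all small instances. Score vectors: increasing
(1,2,3), decreasing (3,2,1), concave ∩ (1,2,1), convex ∪ (2,1,2) — the
minimal canonical patterns. Applying a rank test to B-sized bootstrap
distributions makes the effective n enormous and p-values tiny; the test
is used here, as in the study design it follows, as a patterned-trend
detector rather than a calibrated subject-level test.

**Classification.** Per comparison: monotonic label = the more significant
of increasing/decreasing at 0.05; umbrella label = ∩/∪ if significant,
else "absence of empirical support"; endpoints described as pos/neg/≈0
from the within-group permutation verdicts; strongest group = argmax of
|median WINcorr| with exact ties reported as `tie`; strength bands
|r| < 0.2 negligible, < 0.4 weak, < 0.6 medium, ≥ 0.6 strong (anchored to
the "medium-strong ≥ 0.4" convention). Tests are reported at nominal 0.05
without multiplicity correction; the trend table carries the count of
significant whole-cohort comparisons so readers can judge the burden.

## Parameters

| parameter | default | meaning |
|---|---|---|
| γ | 0.1 | Winsorization proportion per tail |
| B | 5000 | bootstrap replicates (study setting; drivers use 1000) |
| n_perm | 5000 | permutations per test (drivers use 500–1000) |
| level | 0.95 | BCa coverage |
| contamination | 0.01, 6 SD | outlier fraction and magnitude |
| seed | — | master seed; all substreams derive from it |

## Problem sizes and determinism

The analysis drivers and the acceptance script run the full n = 1154
cohort with B = 1000 and n_perm = 500–1000, and average calibration
recovery over 200 cohorts — sizes at which every Monte-Carlo check has
standard error well below its tolerance while a full run stays in the
seconds-to-a-minute range. The study-scale B = n_perm = 5000 setting runs
unchanged in a few minutes. Identical seeds yield byte-identical CSV
outputs.

## What the synthetic cohort does and does not show

The generator reproduces the study's design exactly (counts, strata,
demographic composition), its published correlation values by calibration,
additive demographic biases, and heavy-tailed contamination. It does not
reproduce: the real proxies' skewed marginals (spectral powers are
generated Gaussian, not log-normal), non-additive or continuous-age
demographic effects, the unreported proxy–proxy correlation structure
(single-factor by construction), between-group mean shifts in the proxies
(so whole-cohort correlations are pure mixtures of the group ones), or any
mechanistic SAP–autonomic coupling. Passing tests therefore demonstrate
that the statistical machinery is correct and that the published
correlation pattern, when present, is detected and classified as reported
— not that the physiological findings themselves are reproduced from raw
data.

## Known limitations

- The exact construction of the published ANSI (reference-population
  weights) is not public; the rank-average-rerank synthesis here is this
  package's documented approximation.
- Grouping uses a single clinic SAP value; the study records both
  sphygmomanometer SAP and Finometer SAP mean, and the generator's `sap_v`
  proxy is generated like any other proxy, deliberately not tied to the
  grouping variable.
- BCa acceleration uses the delete-one jackknife on the full chain; for
  group scopes the deleted subject affects other groups only through the
  shared adjustment/rank reference, which makes `a` slightly conservative
  for small groups.
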