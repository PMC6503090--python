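# barotrend

Trend analysis of how systolic-arterial-pressure (SAP) groups modulate the
correlation between the cardiac baroreflex **α index** and
heart-rate-variability (HRV) autonomic proxies.

## The problem

The baroreflex gain α (ms/mmHg, from the RR/SAP cross-spectrum) is clinically
valuable but costly to measure; plain HRV indices and the composite **ANSI**
(a percent-ranked synthesis of RR mean, RR variance and the stand–rest shift
of normalized LF power) are cheap. How strongly α correlates with these
proxies — and whether the correlation strengthens or weakens across the
normotensive (Nt, SAP < 130 mmHg), pre-hypertensive (preHt, 130–139 mmHg) and
hypertensive (Ht, ≥ 140 mmHg) states — determines how far the cheap indices
can stand in for the expensive one. The interesting possibility is an
**umbrella (curvilinear) trend**: correlations that peak (∩) or dip (∪) in
the pre-hypertensive transition state rather than changing monotonically.

`barotrend` implements the full statistical chain for a 1154-subject
cross-sectional cohort design, plus a calibrated synthetic-cohort generator
standing in for the original (non-deposited) subject-level data:

1. **Adjustment** — each variable is replaced by its residual from a
   saturated two-way ANOVA on gender × age-class (fitted value = cell mean),
   removing demographic bias; ANSI is computed from the adjusted components.
2. **Robust correlation** — the γ-Winsorized correlation
   (γ = 0.1): both vectors are clamped at their ⌊γn⌋-th order statistics
   before applying the Pearson formula, taming outlying subjects.
3. **Stratified balanced bootstrap** — B replicates that preserve the seven
   SAP-stratum counts exactly, with each subject drawn exactly B times
   across the ensemble; adjustment and ANSI are *recomputed on every
   replicate*, and WINcorr is evaluated for all 14 α-vs-proxy comparisons
   overall and within the three SAP groups.
4. **Inference** — bootstrap medians with BCa 95% confidence intervals,
   permutation tests of zero correlation, and the Hettmansperger–Norton
   rank test against monotonic (1,2,3)/(3,2,1) and umbrella (1,2,1)/(2,1,2)
   patterned alternatives, summarized in a synoptic trend classification.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1     # cohort -> results/cohort.csv
python analysis/02_adjust_cohort.py                # adjusted CSV + sanity read-out
python analysis/03_bootstrap_inference.py --seed 1 # B=1000 bootstrap + inference
python analysis/04_render_figures.py               # heatmap/ridgeline/synoptic
```

The third step prints:

```
alpha-ANSI median WINcorr by group: Nt +0.464, preHt +0.629, Ht +0.422
alpha-ANSI umbrella: concave (HN concave p = 0); strongest group: preHt
preHt strongest in 10 of 14 comparisons
```

Read: the median bootstrap Winsorized correlation between adjusted α and
ANSI rises from 0.46 (Nt) to 0.63 (preHt) and falls back to 0.42 (Ht); the
Hettmansperger–Norton test against the concave pattern is significant, so
the trend is classified as a ∩ umbrella with the pre-hypertensive group at
the apex — the transition pressure state is where the baroreflex–HRV
coupling is tightest, in 10 of the 14 examined comparisons.

The same chain is scriptable via the `barotrend` CLI
(`barotrend simulate | analyze | report`) or the library API
(`generate_cohort`, `adjust_cohort`, `run_analysis`, `render_reports`).

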