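# Methods

## The scoring model

MIPSS-R treats a patient's prognosis as driven by two summary scores: the
IPSS-R total `r` (cytogenetics + blasts + hemoglobin + platelets + ANC, on
the half-point grid 0–10) and a mutation score `m` ∈ {0, 1, 2, 3} from the
count of distinct mutated genes, with *SF3B1*-only privileged as low risk.
Under a proportional-hazards assumption the log hazard of death is linear
in both, and the combined score is the estimated linear predictor

    MIPSS-R = β̂_mut · m + β̂_ipssr · r,   defaults β̂ = (1.047, 0.641).

The achievable scores form an 84-point grid {1.047·m + 0.641·r}.  Risk
groups are quintiles of the cohort score distribution, reported the way
clinical papers report them: as the (min, max) of observed scores per
quintile.  The reference ranges are 1.28–2.24, 2.33–3.93, 4.02–4.34,
4.57–5.30 and 5.62–8.59.

**Classification convention.**  Published per-group ranges leave gaps
(e.g. 2.24–2.33) because not every grid point was observed.  We place the
decision thresholds at the midpoints of those gaps — 2.285, 3.975, 4.455,
5.460 — making the classifier total over the score line; scores below the
lowest range clamp to very-low and above the highest to very-high.  A
nearest-range or lower-range rule would differ only inside the gaps;
midpoints are symmetric and deterministic.  Classification always uses the
full-precision score; the two-decimal display value (half-away-from-zero
rounding, decimal-representation based so grid values like 0.3205 round as
printed) is cosmetic.

**Component conventions.**  IPSS-R bins are transcribed with their exact
boundary inclusivity (blasts ≤2 → 0, >2–<5 → 1, 5–10 → 2, >10 → 3;
hemoglobin ≥10 → 0, 8–<10 → 1, <8 → 1.5; platelets ≥100 → 0, 50–<100 →
0.5, <50 → 1; ANC ≥0.8 → 0, else 0.5).  The combination uses the **raw
IPSS-R total**, not the 1–5 category index: the reference quintile
endpoints (8.59 in particular) are reachable only with raw totals.
Mutation counting uses distinct genes, not variants; callers with
variant-level data can pass `n_mutations=` to count variants, in which
case the *SF3B1* privilege requires a single variant.  Genes outside the
configured panel are dropped with a warning before counting.  The default
31-gene panel is a representative roster of recurrently mutated MDS genes
(a synthetic stand-in — targeted panels differ between laboratories); any
panel can be loaded from a one-symbol-per-line file, or disabled.

**Karyotype handling.**  The ISCN parser covers the subset needed for
risk grouping: modal number and sex field (not counted as abnormalities;
an explicit `-Y` is), numeric gains/losses, `del`/`i`/`inv`/`t` with
band-level detail reduced to the chromosome arm, clinical shorthand like
`5q-`, and generic structural tokens that fall into the "any other"
classes.  Unknown tokens raise a parse error naming the token — never a
silent intermediate.  Complex means ≥3 abnormalities (exactly 3 → poor,
more → very poor).  Mosaic karyotypes are classified on the worst clone
(conservative).  A double carrying both del(5q) and −7/del(7q) is graded
poor, the worse of its two rules.  Composite karyotypes, `idem`, and
breakpoint-level semantics are out of scope.

## Development pipeline

`derive_weights` fits a multivariate Cox model of overall survival on
(`mut_points`, `ipssr_total`); the coefficients become the weights,
reported at three decimals but used at full precision.  `derive_bins`
splits scores at the empirical 20/40/60/80th percentiles; ties at a
boundary travel together (so groups never interleave), each group is
reported as its observed (min, max), and binning refuses score vectors too
discrete to form five separated groups.  Because classification thresholds
are gap midpoints, `derive_bins` → `classify_mipssr` reproduces quintile
membership exactly for continuous scores.  Note that scored cohorts lie on
the 84-point grid, whose atoms can make exact 20% splits impossible — the
20%±2% balance property is a statement about continuous score
distributions.

## Validation statistics

- **Kaplan–Meier / log-rank / Cox PH** are standard fits and go through
  `lifelines` (Newton–Raphson tightened to coefficient precision 1e-9).
  The median is the first event time with S(t) ≤ 0.5; when the curve never
  gets there the median is reported as `>{max follow-up}`.  Ties use
  Efron's method (the survival-analysis default); `ties="breslow"` is
  available via a direct BFGS maximization of the Breslow partial
  likelihood with a finite-difference observed-information matrix.
- **LASSO-Cox** rides on scikit-survival's Coxnet coordinate descent.
  Covariates are standardized internally and coefficients reported on the
  original scale.  The lambda grid is 100 log-spaced values from the
  all-zero penalty down four decades; cross-validation uses 10 folds
  stratified by event status with a required seed, scoring each lambda by
  held-out partial-likelihood deviance (−2·logPL); `lambda_min` minimizes
  the mean.  A requested lambda of 0 maps to a numerically negligible
  penalty (the solver needs a positive one); on tie-free data the result
  agrees with the unpenalized fit to <1e-4.
- **Time-dependent ROC** is the Kaplan–Meier based cumulative-case /
  dynamic-control estimator: with S the all-sample KM curve and S_c the KM
  curve of the subgroup with marker > c,
  sens(c) = (P(M>c) − P(M>c)·S_c(t)) / (1 − S(t)) and
  spec(c) = (S(t) − P(M>c)·S_c(t)) / S(t), cutoffs at every observed
  marker value, AUC by the trapezoid rule with (0,0) and (1,1) appended.
  This estimator is implemented here because installed packages provide
  only the IPCW variant, a different statistic.  It is invariant under
  strictly monotone marker transforms; like the original it is not
  guaranteed monotone in c under heavy censoring.  The default horizon is
  the cohort's median follow-up.  AUC values are horizon- and
  censoring-dependent, so published AUCs are not comparable across
  cohorts without the same horizon convention.

## Synthetic cohorts

`simulate_cohort` emulates a real-world MDS cohort's marginals: hemoglobin
normal (mean 9.2, SD 2.4 g/dL, clipped 3.3–15.2), platelets and ANC
log-normal (medians 81.5 and 1.4 ×10⁹/L, log-SD 1.0 / 0.9, clipped to
2–987 and 0.07–28), blasts exponential (scale 3%, capped at 28%), age
normal (70 ± 12, 24–91), ~69% male.  Mutations are independent Bernoulli
per gene with prevalences led by ASXL1 0.315, TET2 0.278, TP53 0.185,
SRSF2 0.148, SF3B1 0.148 and a 4% background for the rest of the panel;
cytogenetic categories are drawn with P(very good, good, intermediate,
poor, very poor) = (0.02, 0.66, 0.15, 0.08, 0.09), putting ~9% of
patients in complex-karyotype territory.  Overall survival is Weibull
proportional hazards with log hazard 1.047·m + 0.641·r, centered at a
typical patient (m=2, r=3.5) so the 30-month scale parameter is that
patient's characteristic survival; censoring is administrative, uniform
over a 60-month window.  Event times are kept at full float precision so
simulated data are tie-free.

Components are sampled **independently** — no anemia–blast correlation, no
karyotype–mutation linkage, no AML-progression process.  The cohorts are
therefore adequate for testing scoring arithmetic and the statistical
machinery (the survival link is exactly the model the score assumes), but
they are not epidemiologically realistic, and passing tests say nothing
about how well the score transports to real patients.

## Problem sizes and numerical checks

The test suite exercises weight recovery at n = 3000 (±0.15 tolerance on
both coefficients), log-rank type-I error with 1000 replicates of 5×30
exponential samples (acceptance band 3–7% at α = 0.05), null-marker AUC at
n = 2000 (0.5 ± 0.05), and LASSO selection stability over repeated CV
seeds at n = 600.  Oracles are independent re-derivations written in the
tests: closed-form product-limit values, the textbook O−E/V log-rank
table, 1-D partial-likelihood maximization by bounded scalar search, and
exhaustive ROC cutoff enumeration on uncensored toys.

## Known limitations

- The mutation score ignores *which* genes are mutated beyond *SF3B1*;
  gene-specific hazards (TP53 in particular) are deliberately traded away
  for robustness to heterogeneous mutation patterns.
- The ISCN parser is a pragmatic subset; exotic rearrangement nomenclature
  must be pre-mapped to `cyto_category`.
- Quintile bins derived on small or heavily discretized cohorts are
  unstable; the package raises rather than guessing when groups cannot be
  separated.
- Efron/Breslow agreement and the LASSO unpenalized limit are exact only
  without tied event times.
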