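# Methods

This note records the algorithms, the rationale behind every tunable
default, and the known limitations. All thresholds are package design
choices exposed as parameters (`HabParams`, `DeParams`, `DifferentialGate`,
`PipelineConfig`); nothing is hard-coded.

## Conventions

- **Time.** Activity is a vector of wheel counts in fixed-width bins whose
  width divides 24 h (default 6 min). Bin 0 starts at ZT0 = lights-on; the
  light phase is ZT < `light_hours` (default 12). Missing bins are NaN.
  "Morning" for the delayed-activity index is ZT0–6, the first quarter of
  the day immediately after lights-on, where a nocturnal animal is normally
  quiescent.
- **Effect sizes.** Every test returns an `EffectSize` with a nonnegative
  magnitude, a separate direction, and a conventional label using strict
  thresholds: Cohen's *d* > 0.01/0.2/0.5/0.8 (very small/small/medium/
  large), rank *r* and φ > 0.1/0.3/0.5, η² > 0.01/0.06/0.14. Cohen's *d*
  uses the pooled, df-weighted SD; rank *r* = |Z|/√N with the tie-corrected
  normal approximation's Z (no continuity correction); η² is classical
  SS_effect/SS_total (partial η² is reported alongside for ANOVA).
- **Exact vs asymptotic rank tests.** Mann–Whitney and the signed-rank test
  use exact enumeration when N ≤ 12 and the data are tie-free, otherwise
  the tie-corrected normal approximation. The switch point is the largest
  size at which full enumeration is instantaneous; both regimes are tested
  against brute-force oracles.

## Hyperactivity-bout (HAB) detection

A HAB is operationally > 6 h of outlier-level running. The detector:

1. computes rolling `window_hours` (default 1 h) sums of counts; windows
   with more than `max_missing_frac` (20 %) missing bins are not callable;
2. flags windows whose sum exceeds the animal's own Tukey fence
   Q3 + 1.5·IQR over all callable window sums (the conventional box-plot
   outlier rule, applied per animal so baselines self-normalize);
3. merges maximal runs of flagged windows across gaps of at most
   `merge_gap_hours` (1 h) and takes the union of flagged windows' bins as
   the episode extent;
4. keeps episodes spanning at least `min_duration_hours` = 6 h (closed
   bound: exactly 6 h qualifies). The score is (peak window sum − fence)/IQR.

**Why 1-h windows.** With windows as long as the 6-h duration floor, the
extent of a detected bout is smeared by up to one window length on each
side: a genuine 12-h bout inflates to ~22 h (boundary Jaccard ≈ 0.53) and a
3-h burst can flag a > 6-h run of windows (a false call). One-hour windows
keep the boundary error below ~1 h per side, which yields median boundary
Jaccard ≈ 0.93 for 6–24 h bouts and no calls for 3-h bursts, while still
averaging over enough bins (10 at the default resolution) to suppress
single-bin noise.

Because flagging compares each window to quantiles of the same animal's
window-sum distribution, detection is invariant to rescaling the counts
(different wheels/encoders). At least 14 days of recording are required so
the reference distribution reflects baseline, not the episode.

## Depression-like (hypoactivity) episode detection

1. Daily totals are smoothed with a `smooth_days` = 3 centered moving
   average (edge-padded), damping single-day dips without blurring
   multi-week structure.
2. Baseline is the median smoothed daily total. Days below
   (1 − δ)·baseline are flagged; runs of ≥ `min_duration_days` = 14
   consecutive flagged days are candidate episodes. The baseline is then
   re-estimated once excluding candidate days — a long episode otherwise
   drags the median down and erodes its own threshold margin — and the
   flagging repeated.
3. The episode score is the mean fractional activity deficit.

**Why δ = 0.3.** Episodes of interest halve daily activity. A threshold at
exactly 50 % of baseline puts such episodes on the decision boundary: with
realistic day-to-day variability about half of the episode's days fall
above the line and 14-day consecutive runs never assemble. Flagging below
70 % of baseline (δ = 0.3) detects 50 % reductions with wide margin while
day-level noise (lognormal σ ≈ 0.15, further reduced by 3-day smoothing)
keeps the null false-call rate at ~0. At least 8 weeks of data are
required so the median baseline cannot be dominated by one episode.

## Delayed-activity index

The mean, over days in a window, of the fraction of that day's activity
falling in ZT0–`morning_hours` (default 6). Zero-activity days are
excluded; an all-zero window returns NaN (flagged undefined) rather than a
silent 0. The pipeline contrasts the index during each detected episode
with the flanking `flank_days` = 14-day windows, paired within animals
(Wilcoxon signed-rank).

Episode frequency is reported per 183 observed days ("per 6 months").

## Differential lipids and the selection gate

Abundances are log₂-transformed with a per-lipid pseudocount of half the
minimum positive value (raw scale by flag). Each lipid gets a two-sample
*t*-test (Welch default, Student by flag) and a signed pooled-SD Cohen's
*d*; lipids with zero pooled variance are marked untestable and excluded
from both selection and the BH family. A lipid is *selected* when
*P* < `p_max` (0.05) **and** |*d*| > `d_min` (0.8). BH-adjusted p-values
are reported alongside but the gate itself is unadjusted by design: the
effect-size clause is the multiplicity control in this convention.

**Gate behaviour at n = 8/8.** |t| = |d̂|·√(n/2), so significance at the
0.05 level (|t| > 2.145, df 14) already implies |d̂| > 1.07. The |d̂| > 0.8
clause is therefore vacuous at this sample size and the null selection
rate equals the 5 % test level (measured 0.048). The gate's effect-size
clause only binds at n ≳ 15 per group. Relatedly, the per-lipid sampling
SD of d̂ at 8/8 is ≈ 0.52 (≈ √(2/ñ + d²/2N)), so effect-size recovery is a
statement about central tendency: the *median* estimated |d| across effect
lipids and seeds lands within ±0.3 of the injected value, while individual
lipids scatter far more widely.

## Enrichment

For each lipid class (and each distinct acyl chain, e.g. 22:6), membership
versus selection forms a 2×2 table tested with Fisher's exact test; φ is
the effect size (flagged undefined on zero margins, where p = 1) and BH
correction runs across categories within each family. A lipid with k
distinct chains counts once per chain.

## Ordination

- **PCA**: sklearn on centered (optionally unit-variance) log₂ abundances,
  full SVD, components truncated to matrix rank with a warning.
- **Hierarchical clustering**: Ward linkage on Euclidean distances between
  samples (scipy), exported as Newick.
- **OPLS-DA**: the orthogonal deflation is implemented directly (sklearn's
  `PLSRegression` serves only as an independent cross-check in the test
  suite). With a centered ±1 class vector y, each orthogonal component's
  weight is built by projecting the first PLS weight's complement
  (w_orth ∝ p − (wᵀp)w), so orthogonal scores are exactly uncorrelated
  with y (machine precision); after removing `n_orthogonal` (default 1)
  such components, a single predictive component is fit and lipids are
  ranked by |predictive loading|, flagging the top ⌈`top_fraction`·n⌉
  (1 % of 464 = 5). With `n_orthogonal` = 0 this reduces to one-component
  PLS-DA.
- **Model validation**: with far more lipids than samples the fitted R²Y
  saturates near 1 for *any* labels, so permutation testing on fitted R²Y
  cannot discriminate. Validation therefore uses leave-one-out
  cross-validated Q²Y (`oplsda_q2y`), compared against its label-permuted
  null distribution (`oplsda_permutation_q2y`); R²Y is still reported.
- **Distance ANOVA**: two-way ANOVA (η² per factor) on each sample's
  Euclidean distance to a reference centroid in log₂ space. The reference
  defaults to the centroid of the first level of factor A (the control
  group): distance to the *grand* centroid is blind to a balanced
  two-group displacement, because both groups end up equidistant from the
  pooled mean by symmetry. The grand centroid remains available via
  `reference_level="grand"`.

## Statistical core notes

- The two-period crossover repeated-measures ANOVA is OLS with subject
  fixed effects + period + treatment (type-II SS); the treatment F is
  tested against the within-subject residual and η² = SS_treat/SS_total.
  Sequence effects are absorbed by the subject terms. Subjects with
  incomplete data are excluded with a warning.
- Type-I calibration regimes (acceptance criterion "each test in
  [0.04, 0.06] at 10,000 null replicates") are chosen where the nominal
  level is attainable: t at 8/8 on normals, U at 20/20, signed-rank at
  n = 30, Fisher on binomial(150, ½) margins. Exact conditional tests are
  intrinsically conservative at small margins — a property of the tests,
  not the implementation — so small-sample regimes cannot sit inside that
  window.

## Simulators

- **Actigraphy**: square (or cosine) 12:12 circadian mean profile
  (dark 50, light 2 counts per 6-min bin ≈ 6,000 revolutions per night),
  negative-binomial bin noise via a gamma–Poisson mixture (size k = 10,
  var = μ + μ²/k), and a day-level log-normal factor (σ = 0.15,
  mean-corrected) for day-to-day variability. HABs set the mean to
  `amplitude`×dark rate around the clock (manic running ignores the
  light/dark cycle); depression-like episodes multiply the profile by
  `amplitude` and move a `light_redistribution` fraction of the remaining
  expectation into ZT0–6 (the phase-delay signature). Episode specs
  validate the definitional bounds (HAB 6–24 h, episodes ≥ 14 days) and
  cannot overlap. `draw_spontaneous_habs` draws bouts from a per-day
  hazard for cohort-frequency studies.
- **Lipidomics**: 464 lipids in a fixed 26-class composition with acyl
  chains sampled from a 29-chain pool; abundances are log₂-normal
  (baseline mean N(10, 2), within-group SD σ = 0.4). An effect shifts its
  member lipids (a class, all carriers of a chain, or an explicit id set)
  by direction·d_target·σ in log₂ space for the second group, so the
  population Cohen's d on the analysis scale equals d_target exactly.
  Ground truth (shift, d, membership) is returned with every table.
- `write_fixture_bundle` writes CSV/TSV fixtures plus a JSON manifest;
  regeneration from the same configs is byte-identical.

## Limitations

- Detectors assume a stable light schedule; free-running (DD) rhythms and
  phase-shifting protocols are out of scope.
- The HAB fence assumes episodes occupy a minority of the record; an
  animal manic for most of six months raises its own fence.
- The simulators model stationary baselines — no aging trends, estrous
  modulation, or wheel failures beyond missing bins.
- The lipid simulator draws lipids independently (no correlation
  structure); clustering/ordination power estimates on simulated data are
  therefore optimistic.
- Distance ANOVA reduces the lipidome to one scalar per sample; it detects
  displacement magnitude, not direction, and the reference-centroid choice
  is part of the model.
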