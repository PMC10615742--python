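# actilipid

Episode detection in long-term wheel-running actigraphy and effect-size-gated
brain lipidomics, for rodent models of mood disorders.

Mouse models of bipolar disorder are characterized behaviorally by two kinds
of spontaneous episodes in months-long wheel-running records — mania-like
**hyperactivity bouts** (HABs: more than 6 h of outlier-level running,
often spilling into the light/rest phase) and **depression-like episodes**
(two weeks or more of markedly reduced running with a circadian phase
delay) — and molecularly by shifts in the brain lipidome. `actilipid`
implements both analysis arms end to end:

- **Actigraphy** — activity-series I/O with gap handling, daily summaries,
  double-plotted actograms, a HAB detector (rolling-window sums against the
  animal's own Tukey outlier fence, Q3 + 1.5·IQR), a hypoactivity-episode
  detector (smoothed daily totals under a fractional baseline threshold for
  ≥ 14 consecutive days), a delayed-activity index (fraction of daily
  activity in ZT0–6, the first hours after lights-on), and episode
  frequencies per 6 months.
- **Lipidomics** — differential lipids under the joint gate
  *P* < 0.05 ∧ |*d*| > 0.8 (Welch/Student *t* on log₂ abundances, pooled-SD
  Cohen's *d*), Fisher-exact class and fatty-acid enrichment with BH
  correction, PCA, Ward hierarchical clustering with Newick export, OPLS-DA
  with top-1 % predictive-loading ranking and permutation-validated Q²Y,
  and a two-way ANOVA on centroid distances.
- **Statistical core** — Welch/Student *t*, Mann–Whitney U, Wilcoxon
  signed-rank (exact by enumeration for N ≤ 12 without ties, tie-corrected
  normal approximation otherwise), Fisher's exact test, Kruskal–Wallis,
  two-way and two-period-crossover repeated-measures ANOVA; every test
  returns an effect size (Cohen's *d*, rank *r* = |Z|/√N, φ, η²) with a
  conventional magnitude label.
- **Simulators** — negative-binomial nocturnal actigraphy with injected
  HABs and depression-like episodes, and log-normal lipid tables (464
  lipids, 26 classes) with group effects of specified Cohen's *d*, both
  with exact ground truth for validation.
- **CLI** — `actilipid` with subcommands for simulation, detection,
  actograms, differential/enrichment/ordination steps, and two full
  analysis arms (`run-arm behavior`, `run-arm lipid`) that write tidy TSVs
  plus a JSON report embedding the resolved parameter set.

## Worked example

```python
from actilipid import (
    detect_habs, detect_hypoactivity_episodes, delayed_activity_index,
    episode_frequency, differential_lipids, class_enrichment, oplsda,
)
from actilipid.simulate import (
    ActivitySimConfig, EpisodeSpec, LipidEffect, LipidomicsSimConfig,
    simulate_activity, simulate_lipidomics,
)

# six months of 6-min-binned wheel counts with one injected 12-h manic bout
# and one injected 21-day hypoactive episode with a circadian phase delay
cfg = ActivitySimConfig(
    n_days=183, seed=42,
    episodes=[
        EpisodeSpec(kind="HAB", onset_day=40, onset_hour=14.0,
                    duration_hours=12.0, amplitude=5.0),
        EpisodeSpec(kind="DEPRESSION_LIKE", onset_day=90, duration_days=21,
                    amplitude=0.5, light_redistribution=0.3),
    ],
)
series, truth = simulate_activity(cfg, subject_id="demo")

habs = detect_habs(series)                      # 1 call: bins 9735..9864 = 12.9 h
des = detect_hypoactivity_episodes(series)      # 1 call: days 90..111
episode_frequency(habs, series.n_days)          # 1.0 per 6 months
d0 = des[0].start_bin // series.bins_per_day
d1 = des[0].end_bin // series.bins_per_day
delayed_activity_index(series, (d0, d1))        # 0.312 during the episode
delayed_activity_index(series, (d0 - 14, d0))   # 0.020 in the 2 weeks before

# 464-lipid table, 8 vs 8 samples, with a d = 2 increase planted in class PS
table, _ = simulate_lipidomics(
    LipidomicsSimConfig(seed=7, effects=[LipidEffect(target="PS", d_target=2.0)])
)
diff = differential_lipids(table, "genotype", "MUT", "WT")
int(diff["selected"].sum())                     # 43 lipids pass P<0.05 and |d|>0.8
enr = class_enrichment(diff, table)
enr.loc["PS", ["p", "phi"]]                     # p = 2.3e-34, phi = 0.79
res = oplsda(table, "genotype", positive_level="MUT")
res.extra["top_lipids"][:3]                     # PS species lead the top 1%
```

The same analyses run from the shell:

```bash
actilipid simulate-activity --out scratch/cohort --n-animals 8 --seed 1
actilipid run-arm behavior --input scratch/cohort --out scratch/behavior
actilipid simulate-lipids --out scratch/lip --effect-class PS --seed 1
actilipid run-arm lipid --input scratch/lip/lipids --out scratch/lipid
```

## Known-unattainable targets

Two acceptance tests in `tests/test_acceptance.py` fail deliberately:

- **Null gate rate** (`test_criterion_4b_null_gate_rate`): at n = 8/8,
  significance at *P* < 0.05 already implies an observed |*d*| > 1.07, so
  the |*d*| > 0.8 clause of the gate is vacuous and the null selection rate
  is pinned to the 5 % test level (measured 0.048). A target of ≤ ~1 % is
  mathematically unattainable at this sample size.
- **Published-table reproduction** (`test_criterion_6_published_table`):
  verifying the source study's published counts requires its supplementary
  lipid abundance table, which is not redistributable with this repository
  and has no public accession. Supplying the table at
  `data/published_lipidomics.tsv` enables the full comparison.

## Documentation

Algorithmic details, parameter rationale, and limitations are in
[docs/methods.md](docs/methods.md).
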