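# lifespace

Lifespace — the geographic area in which a person lives and conducts
their activities — is a gerontology construct that reflects community
mobility, health and participation. Traditionally it is self-reported;
with a smartphone in the pocket it can be measured passively from GPS.
This package implements a GPS-based Lifespace analysis for small
clinical cohorts (its motivating use case is people with Parkinson's
disease and matched controls): it infers each participant's home from
the trace itself, detects trips into the community with a two-state
finite-state machine, summarizes mobility in four per-participant
metrics, compares groups nonparametrically, and produces
privacy-preserving visual summaries. A synthetic-trace generator with
ground truth stands in for raw study data, which cannot be shared, and
backs the validation suite.

## The method

For a trace of timestamped fixes $(t_i, \phi_i, \lambda_i)$, distances
are great-circle (haversine) on a sphere of radius $R = 6371.0088$ km:

$$d = 2R \arcsin \sqrt{\sin^2\tfrac{\Delta\phi}{2} +
\cos\phi_1 \cos\phi_2 \sin^2\tfrac{\Delta\lambda}{2}}$$

**Home** is established mathematically as the statistical mode of the
recorded coordinates: fixes are binned on a $10^{-4}\,°$ (~11 m) grid
and the modal cell's point mean is home. **At home** means within
500 m of that point — a deliberately cautious radius given ~10 m
outdoor (and far worse indoor) smartphone GPS accuracy.

**Trips** come from a finite-state machine with two states — subject
at home (SH) and subject not at home (SNH) — stepped through the
fixes in time order. SH→SNH fires at the first fix beyond 500 m
(departure timestamp recorded); SNH→SH at the first fix back inside
(return). Excursions shorter than 15 minutes are ignored as GPS
artifacts. Four metrics per participant follow: furthest distance from
home (km), mean daily distance (km), percentage of *recorded* time at
home, and qualifying trips per week (count × 7 / recorded days).
Groups are summarized by median and IQR and compared with a
Mann-Whitney U test (midranks, tie-corrected normal approximation);
PD participants are additionally ordered by baseline partial-UPDRS
severity.

## Worked example

```python
import lifespace as ls

cfg = ls.SimulationConfig(seed=3, n_days=5)      # 5 recording days
trace, truth = ls.simulate_participant(cfg)
res = ls.LifespaceModel(trace).fit()
print(res.summary())
print("home error (m):", 1000 * ls.haversine_km(res.home_estimate.home,
                                                truth.true_home))
```

prints

```
Lifespace results — participant sim-3
  config hash            6605d8e0c6d3
  fixes / sessions       7573 / 4
  recorded days          4
  trips (qualifying)     1 (1)
  max distance from home 3.46 km
  mean daily distance    0.90 km  [max_home_distance]
  % recorded time at home 94.24 %
  trips per week         1.75
home error (m): 6.27...
```

One of five simulated days was skipped (a day the participant did not
switch the logger on), so four recording sessions and four recorded
days appear. The single planted trip reached 3.46 km from home and is
the one qualifying trip; with the phone recording 4–6 h per day mostly
spent at home, 94% of recorded time is within the 500 m radius, and
the inferred home lands ~6 m from the true one — well inside the 10 m
GPS noise. Cohort-level use is the same pattern over many traces
(`fit_cohort`, `cohort_metrics_frame`, `compare_cohort`), or from a
shell:

```bash
lifespace simulate --seed 1 --out sim/
lifespace compute sim/pd*.csv sim/ct*.csv --out out/
lifespace compare --metrics out/metrics.csv --meta sim/metadata.csv --out cmp/
lifespace viz sim/pd01.csv --out plots/
```

All reporting paths emit mean-subtracted coordinates only; absolute
positions never leave the compute path unless `--unsafe-raw` is given.

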