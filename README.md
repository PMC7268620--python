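# nestfate

Locate breeding sites in GPS trajectories of central-place foragers, and
estimate whether each breeding attempt succeeded — straight from the
movement data.

Many birds (and some denning mammals) become central-place foragers while
breeding: they leave the nest to forage and return to incubate or
provision. Two consequences for their trajectories are exploited here:

1. **The nest is a recurrently revisited location.** Part I scans a track
   with a circular buffer of radius *r* around every fix and summarises
   each revisited location with three diagnostic metrics: the maximum
   number of consecutive days visited, the percentage of days visited
   between first and last visit, and the percent of fixes at the location
   on its best-attended day. Nests score high on all three; foraging
   patches, roosts and perches usually do not. Thresholds can come from
   prior knowledge or be learned from tracks with known nests via a
   classification tree (CART) pruned by minimum cross-validated relative
   error. Temporally overlapping nest candidates of one bird are resolved
   by keeping the most visited.

2. **Revisits persist until the attempt fails.** Part II converts the
   track around a detected nest into a daily record (N_t fixes, Y_t of
   them at the nest) and fits a hierarchical Bayesian survival model with
   imperfect detection, akin to a Cormack–Jolly–Seber model:

   z_t ~ Bernoulli(z_{t−1} · φ_{t−1})  (latent alive/failed, absorbing death)
   Y_t ~ Binomial(N_t, z_t · p_t)      (visits detected only while alive)
   logit(φ_t) = β_φ0 + β_φ1·t,  logit(p_t) = β_p0 + β_p1·t

   The fate of an attempt is P = Pr(z_T = 1), the posterior probability it
   was still alive on the last day T of a full breeding cycle. Missing
   days (N_t = 0) carry no information; declining nest attendance is
   absorbed by the day trend in p_t rather than mistaken for failure.

A synthetic-data module simulates ground-truthed central-place-forager
tracks (daily foraging loops, declining attendance, failure at a planted
day, wandering non-breeders, daytime-only schedules, fix failures), so the
whole pipeline is testable without any field data.

## Worked example

```python
import nestfate as nf

# simulate a breeder (60-day cycle, hourly fixes) and find its nest
sc = nf.SimScenario(track_id="b1", t_full=60, seed=1)
track, truth = nf.simulate_track(sc)
cands = nf.find_revisited_locations(track, nf.BufferSpec(40.0))
top = cands[0]
print(len(cands), top.metrics)
# 323 RevisitationMetrics(consec_days=60, perc_days_vis=100.0,
#     perc_top_vis=100.0, n_fixes_in=668, first_day=2021-04-01, last_day=2021-05-30)
print(round(nf.haversine_m(top.center_lon, top.center_lat,
                           truth["nest_lon"], truth["nest_lat"]), 1), "m")
# 3.0 m
```

The scan found 323 revisited locations; the most-visited one sits 3 m from
the planted nest and was visited on all 60 consecutive days (100% of days,
with 100% of fixes at the nest on its top day) — exactly the signature the
nest filter keys on. Applying a species rule (e.g. at least 14 consecutive
days and 79% top-day attendance) and resolving overlaps leaves this single
site.

Estimating fate from visit histories:

```python
params = nf.ModelParams(2.0, 0.0, 1.0, -0.05)   # daily phi ~ 0.88, declining p
hists, z = nf.simulate_histories(params, T=40, n_attempts=50, fixes_per_day=10, seed=3)
fit = nf.fit_survival(hists, nf.MCMCConfig(seed=0))
print(fit.converged, {k: round(v, 2) for k, v in fit.rhat.items()})
# True {'beta_phi0': 1.0, 'beta_phi1': 1.01, 'beta_p0': 1.0, 'beta_p1': 1.0}
print(nf.classify_fate(fit, threshold=0.5).head(4))
#   attempt_id   T             P     fate  last_day_above
# 0     sim000  40  3.804683e-86  failure               7
# 1     sim001  40  4.572656e-77  failure               9
# 2     sim002  40  1.597353e-81  failure               8
# 3     sim003  40  1.491230e-15  failure              30
```

With daily survival φ ≈ 0.88 almost every simulated attempt fails, and the
model recognizes that: P is effectively 0, with `last_day_above` marking
how long each attempt was credibly alive (attempt 3 persisted to day 30).
Attempts whose visits persist to day T get P = 1 — an observed visit on
the final day is conclusive.

There is also a CLI (`nestfate simulate | find-nests | learn-rules |
evaluate | buffer-scan | histories | estimate-fate | run-all`) and species
presets (`stork`, `kestrel`, `gull`) bundling breeding seasons, cycle
lengths, tagging adjustments and detection rules.

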