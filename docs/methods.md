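# Methods

## Scope and data model

The unit of analysis is an individual-year track: time-ordered GPS fixes
(timezone-aware timestamps, decimal-degree coordinates) for one animal in
one breeding season. Distances are great-circle metres on a sphere of
radius 6 371 000 m; tracks with pre-projected metric coordinates can opt
into Euclidean distances (`crs="xy"`). "Day" means calendar date in a
configurable timezone (default UTC). Solar-powered tags record primarily
during daylight and day boundaries are never crossed by a foraging trip in
the systems targeted here, so the choice of timezone shifts day labels but
rarely day composition; it is exposed as configuration rather than fixed,
because no universal convention exists for daily aggregation of telemetry.

## Part I — nest-site detection

Every fix is a candidate site center. A circular buffer of radius *r*
(default 40 m, the scale of GPS scatter around a nest) collects the fixes
within it; a location counts as revisited only if its buffer holds fixes
from at least two distinct days. Requiring a distinct-day return (rather
than any later fix after leaving the buffer) is a deliberate choice: the
alternative reading admits every brief stop as "revisited" and adds noise
without adding nests, which are by definition attended across days.
Candidates with identical member sets are collapsed to one representative
(lowest center index); ordering is by visit count, with deterministic
tie-breaks (earlier first day, then lexicographic center coordinates).

Three metrics summarise each candidate:

* `consec_days` — longest run of consecutive days with at least one
  in-buffer fix;
* `perc_days_vis` — % of days visited between first and last visit
  (inclusive span);
* `perc_top_vis` — on the best-attended day, in-buffer fixes as % of all
  of that day's fixes.

By default a day on which the tag recorded nothing at all counts against
`perc_days_vis` and breaks a consecutive run. With `skip_missing_days`
such tag-silent days are ignored entirely (they bridge runs and leave the
denominator); this dialect is appropriate for high fix-failure-rate tags,
where silence says nothing about attendance.

A uniform lon/lat grid (cells conservatively sized to at least *r* in both
dimensions across the track's latitude range) accelerates the buffer scan;
brute force is used for small tracks and whenever geometry makes grid
bounds unsafe (|lat| > 85°, dateline-spanning tracks, projected input).
Correctness is defined by the brute-force pairwise contract, which the
test suite enforces against an independent naive implementation.

Nest filtering applies minimum thresholds on the three metrics, either
supplied (species presets: stork 14 days / 79% top-day; kestrel 7 days;
gull 8 days / 26%) or learned by CART on labeled candidates. Labels come
from on-ground nest coordinates: a candidate within the match radius
(default: the buffer radius, keeping a single spatial scale) is a nest; a
spatially distinct candidate whose visit span overlaps a known nest's span
by at least one day is a non-nest, since the bird was demonstrably
breeding elsewhere — any day of overlap counts as simultaneous. The tree
is grown fully and cost-complexity pruned to the subtree minimizing
cross-validated misclassification error relative to the root (10 folds,
stratified, seeded; ties resolved toward the smaller tree). Nest-leaf
paths become rules — a disjunction of minimum-threshold conjunctions; only
lower bounds are kept (nests are the high-metric class; any upper bound
remains visible in the tree report). When no split on `consec_days`
emerges, the caller must supply a biologically reasonable floor for it:
attempts failing within a handful of days are undetectable in principle,
and silently accepting a 0-day minimum invites false positives.

Overlap resolution is greedy most-visited-first: accept a candidate iff
its visit span is disjoint from every accepted one. Temporally disjoint
sites survive as plausible sequential attempts. Performance is scored as
PPV, sensitivity, FNR (against known nests) and FPR (fraction of
non-breeder tracks with any detection); zero-denominator rates are NaN,
never 0. A buffer-size sensitivity scan re-runs the whole pipeline over a
radius grid (default 10–100 m by 10) and picks the best radius by
sensitivity, tie-broken by PPV.

## Part II — fate estimation

A detected nest and its track become a visit history: day 1 anchors at the
first in-buffer fix; N_t counts all fixes on attempt-day t, Y_t the
in-buffer ones; days without fixes enter as N_t = 0 (a Binomial with zero
trials — no information). T is the species' full-cycle length minus the
nest age at tagging (kestrels tagged just after hatching: 60 − 25 = 35;
gulls in late incubation: 60 − 20 = 40). A track ending before day T is
zero-padded and flagged: it violates the model's assumption that the tag
outlives the attempt, and the flag (plus a warning) surfaces that rather
than hiding it.

The model: z_1 = 1; z_t | z_{t−1} ~ Bernoulli(z_{t−1}·φ_{t−1});
Y_t | z_t ~ Binomial(N_t, z_t·p_t); logit-linear day trends in φ and p
shared by all attempts in the population; Normal(0, variance 1e5) priors
on the four betas (precision 1e-5 on the logit scale). The day covariate
enters unscaled (1..T); sampling internally re-centers the intercepts at
mid-attempt to decorrelate intercept and slope, and maps draws back, so
reported parameters are on the 1..T scale. Survival from day t to t+1 uses
φ evaluated at t. z_1 is fixed to 1: an attempt exists on the day of its
first observed nest visit.

The two-state latent chain is marginalized exactly by the forward
algorithm (probabilities renormalized each step; binomial coefficients
cancel and are dropped; φ and p clipped to [1e-12, 1−1e-12] and per-day
log-emissions floored at −500 purely to keep hopeless parameter proposals
finite). MCMC is adaptive random-walk Metropolis on the four betas:
proposal covariance is the scaled empirical covariance (2.38²/4) with an
acceptance-targeted global scale, adapted during burn-in and frozen after;
the moment accumulators restart halfway through burn-in to shed the
initial transient. Chains start jittered around the posterior mode, found
by a Nelder-Mead polish of crude logistic-GLM estimates (detection from
days up to each attempt's last visit, when the nest was demonstrably
alive; survival from a discrete-hazard view placing each unobserved death
just after the last visit). Mode-starting matters: the likelihood has a
plausible local mode (steep late decline in φ mimicking constant lower φ)
that can trap a cold-started chain. Defaults: 3 chains, 10 000 iterations,
2 000 burn-in; convergence gate split-R̂ ≤ 1.05 and bulk ESS ≥ 400 per
beta (computed with arviz); failing the gate warns and flags the fit,
never silently passes.

Per-attempt fate P = Pr(z_T = 1) averages the exact forward probability at
each retained draw (Rao-Blackwellized over the latent chain), so an
observed visit on day T yields P = 1 exactly in every draw. Smoothed
per-day alive probabilities come from forward-backward; latent
trajectories from forward-filtering backward-sampling (FFBS), which
respects absorbing death by construction (z non-increasing in every
draw). Classification calls success iff P ≥ threshold (default 0.5; 0.9
available for conservative calls) and reports the last day the smoothed
alive probability stayed at or above the threshold.

`exact_fate_probability` exposes the forward computation at fixed
parameters. It is the package's own oracle: the test suite checks it
against exhaustive enumeration of all 2^(T−1) latent paths for T ≤ 12, and
checks FFBS frequencies against it at clamped parameters.

Known limitation: late failure and steeply declining detection are
confounded — a bird that stops being observed at the nest near day T may
have failed or may simply be hard to detect. The model surfaces this as
intermediate P and in the per-attempt alive curves; it does not resolve
it. Detection-performance uncertainty from Part I is reported alongside
but not propagated into Part II.

## Synthetic data

`simulate_track` emulates the data-generating features that matter to the
pipeline, not species-specific movement: daytime-only schedules (06:00 to
20:00 at the tag's nominal interval; 60 min stork-like, 15 min
kestrel/gull-like), independent fix failures (default 10%), Gaussian GPS
scatter (default 10 m), per-day nest attendance on the logit scale
(default logit(0.9), optional day slope — the same parameterization as
the estimator's p_t), abrupt cessation of nest visits after a planted
failure day, and foraging trips to a site pool (3 sites 2–10 km out,
sticky site choice, bounded correlated-random-walk jitter) that produce
genuine non-nest revisited locations. Non-breeders wander the site pool
only; their preset drifts site positions ~200 m per day, mirroring the
loose site fidelity of non-breeding ranges, which caps any one buffer's
consecutive-day run near 2 and keeps controls clean under every species
rule. What the generator does not attempt: habitat, terrain, sex-specific
behavior, continuous paths between sites, or heavy-tailed GPS error — so
passing tests demonstrate algorithmic correctness under the model's own
assumptions, not field performance on real telemetry.

`simulate_histories` draws (z, Y) directly from the model equations,
retaining the truth for calibration; `simulate_fate_cohort` plants known
fates with attendance 0.9 and N_t = 10; `simulate_labeled_metrics` draws
candidate metrics uniformly and labels them by a planted rule conjunction
(default consec ≥ 12 AND top ≥ 60, 5% label noise) for CART recovery
experiments.

## Verification sizes and numerical choices

The test suite runs everything at desk scale, chosen as the smallest sizes
at which each property is sharply testable: revisitation equivalence on
100 random tracks of 30–300 fixes against the naive O(n²) reference;
enumeration cross-checks at T ≤ 12; FFBS-vs-forward agreement at 3
Monte-Carlo σ; CrI calibration with 40 replicates of 50 attempts (T = 40,
N_t = 10) at β = (2.0, 0.0, 1.0, −0.05) with 2 chains × 6 000 iterations —
coverage 37/40 per beta against a ≥ 36/40 gate; planted-fate
classification of 20 + 20 attempts; end-to-end detection on 10 breeders +
5 non-breeders; CART threshold recovery over 100 replicates of n = 400.
Ties, degenerate inputs and zero denominators all have pinned behavior:
deterministic candidate ordering, NaN rates (never 0), hard errors for
Y_t > N_t, duplicate timestamps and single-class CART data.
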