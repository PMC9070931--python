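# Methods

## Model

Each of `n_athletes` agents carries a talent `T_k`, drawn once per run from
a Gaussian with mean `talent_mean = 0.6` and SD `talent_sd = 0.1` and
restricted to `(0, 1]` by **rejection resampling**: out-of-range draws are
redrawn rather than clipped, so the density keeps its Gaussian shape with
no mass piling at the bounds. At these parameter values the truncation is
numerically negligible (total rejected mass ≈ 3 × 10⁻⁵, bias on the mean
< 10⁻³); with other means/SDs the distinction matters and resampling is the
principled choice. Talent is constant for the whole run.

A bout is a sequence of touch opportunities at intervals drawn uniformly
(continuous) on `[touch_interval_min, touch_interval_max] = [2, 60]` s. At
each opportunity:

1. with probability `F_d = double_prefactor · [(1 − ⟨T⟩)/2 +
   (1 − |r₁ − r₂|/N)/2]` a double-hit scores for both fencers, where `⟨T⟩`
   is the opponents' mean talent and `r₁, r₂` their positions in the
   event's initial ranking (entrants renumbered 1..N; `F_d` is a bout-level
   constant);
2. otherwise each fencer draws a chance value `L_k` uniform on
   `[L̄_k − w, L̄_k + w]` (`w = chance_halfwidth = 0.3`) around their
   tournament form `L̄_k ~ U[0.3, 0.7]`, and the higher touch quantity
   `P_k = a·T_k + (1 − a)·L_k` scores. The exact tie `P_1 = P_2` (measure
   zero for `a < 1`, possible at `a = 1` with equal talents) awards no
   touch, keeping the strict comparison.

Pool bouts: 5 hits / one 180 s period. Knockout bouts: 15 hits / three
180 s periods treated as 540 s of cumulative fencing time; the interval in
progress at a period boundary is discarded and redrawn (inter-period breaks
carry no model content). At time expiry the leader wins; a tie triggers the
**priority minute**: a fair coin assigns priority, the first non-double
touch decides, doubles never update the score, and on timeout the priority
holder wins.

Two deliberately configurable corner rules:

* `double_at_match_point = "score"` (default): a double at simultaneous
  match point (e.g. 4–4 → 5–5) stands, the bout counts as tied and goes to
  priority. The alternative `"annul"` (real-rule flavour: doubles at 14–14
  are annulled) is available; it changes nothing measurable at the season
  scale.
* `skipped_event_points = "expire"` (default): the rolling ranking zeroes
  last year's points for an event the fencer skips, mirroring the
  roll-over of a non-cumulative seasonal ranking. `"keep"` retains them
  until replaced.

## Tournament mechanics

Entrants (a multiple of 6; the lowest-ranked surplus fencers are deferred
from the event) are seeded by current overall rank and distributed over
`N/6` pools serpentine-wise. All 15 bouts per pool are fenced; the
after-pool classification sorts by victories/bouts, then hits scored minus
received, then hits scored, then drawn lots. The top
`round(0.7 · N)` qualify (round-half-up, consistent with the canonical
100 → 70 example). With `Q` qualifiers and `S` the largest power of two
≤ `Q`, seeds `S−B+k` and `Q+1−k` (`B = Q − S`, `k = 1..B`) fence a
preliminary round whose winners fill table slots `S−B+1..S`; the table of
`S` uses canonical recursive seeding (seed `s` vs `S+1−s`, top two seeds in
opposite halves). Losers of the round of `2^j` take placements
`2^(j−1)+1 .. 2^j` ordered by after-pool classification; both semi-final
losers are 3rd ex aequo; preliminary losers follow the table field; the
non-qualified 30% fill the bottom in pool order. Points follow the FIE
scale (32, 26, 20, 14, 8, 4, 2, 1, 0.5, 0.25, 0.1 beyond 256th); the
3rd-place band covers places 3–4 so the table stays contiguous even though
place 4 is never awarded.

## Seasons and participation

A season is 8 events; a run is 7 seasons, the first a burn-in excluded
from all statistics by default. Before each season every fencer draws the
number of events to attend from a rank-stratified distribution and then
picks that many event slots uniformly at random.

The default participation model is a synthetic monotone family: binomial
attendance over the 8 events with success probability 0.70 / 0.50 / 0.35 /
0.20 for rank quantile strata 0–10% / 10–30% / 30–60% / 60–100%. This
emulates the observable structure of real junior World-Cup fields — top
fencers travel to most events, the long tail enters a couple — and yields
~210 entrants per event from a 600-strong community, in the range of real
fields. It does **not** reproduce any particular federation's empirical
attendance table; when such a table exists it can be supplied as a
`ParticipationModel` (strata quantiles + per-stratum distributions over
0..8 events), and the reference-data workflow keeps every analysis
independent of the default's exact shape. Events with fewer than 6
planned entrants are skipped with a logged warning and leave the ranking
untouched.

After each event, competitors' points replace the value in that event's
ranking slot, absentees' slots expire to zero, totals are re-summed and
ranks re-drawn (ties, including the zero-point tail, broken by lot).

## Statistics

* **Transition matrices** between consecutive-season rank groups (default
  bins 1–16 / 17–32 / 33–64 / 65–128 / 129–256 / rest, truncated to the
  population size; fully configurable). Both conditioning directions are
  implemented: *forward* rows condition on the start-of-season group,
  *backward* rows (the default) on the end-of-season group — "where did the
  season's top 16 come from?". Per-run matrices give mean and SD across
  runs; pooled counts give the single pooled estimate used for scalar
  summaries.
* **Normalized points curve**: position-wise mean of descending-sorted
  season totals across post-burn-in seasons and runs, scaled to 1 at
  position 1.
* **Placement density**: 2-D Gaussian KDE (`scipy.stats.gaussian_kde`,
  Silverman bandwidth unless overridden) of (initial position, final
  placement) pairs pooled over events, conditioned on either side's top
  16, normalized to unit peak. Degenerate (collinear) samples get a
  microscopic deterministic jitter so the KDE stays defined.
* **Talent vs. rank**: mean and SD across runs of talent at each
  final-season ranking position.

## Calibration

`calibrate_a` grid-searches the talent strength: for each candidate `a`
it runs the full simulator, computes the run-averaged statistic
(transition matrix by default, points curve optionally) and the MSE
against the reference over cells defined on both sides; the argmin wins,
ties going to the smaller `a`. All grid points share one root seed —
common random numbers, which cancels much of the between-candidate noise —
while the reference is generated (or measured) independently.

Parameter recovery at desk scale: with 240 athletes, 7 seasons, 8 events
and 10 runs per grid point, self-generated references at `a = 0.45` are
recovered exactly in ~90% of seed pairs and within one 0.05 grid step
otherwise (the MSE profile is a clean convex curve; adjacent-step misses
are sampling noise between near-equal minima). Smaller designs (e.g. 120
athletes, 4 seasons, 5 runs) recover only to ±1 step reliably.

## Seeding and reproducibility

A single root seed drives a `numpy` `SeedSequence` tree: one child per
replicate run; within a run, dedicated streams for population init and
season-level draws plus one spawned child per tournament. Identical seeds
give bit-identical outputs (asserted in tests); replicates are independent
and could be parallelized without shared state.

## Problem sizes used in the shipped checks

The test suite and the reproduction script use the full Junior Men
configuration (600 athletes, 7 seasons, 8 events, 10 runs) for the
talent-rank and persistence statistics, a 240-athlete reduction for
calibration recovery, and 36–120-athlete communities for structural and
distributional unit checks — sizes chosen so the whole suite completes in
well under a minute while keeping Monte-Carlo error far from the asserted
margins.

## Limitations

* Talent is one-dimensional and static: no aging, learning, injury, or
  entry/exit from the community, so the model cannot express the upward
  bend that real rankings show where young talented fencers enter unranked.
* The participation default is synthetic (above); conclusions about
  attendance-driven effects require a real attendance table.
* All events weigh equally: no championship multipliers, no best-6-of-8
  counting, pools are always of 6.
* Right-of-way weapons (foil, sabre) are out of scope; the touch model has
  no referee error and no 40 ms double-hit hardware window.
* The knockout clock ignores breaks between periods and cards/penalties.
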