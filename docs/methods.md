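# Methods

## The model

`ppsim` simulates the prenatal formation of Peyer's patches (PP) on the
murine gut surface over the 72-hour developmental window from embryonic day
E14.5 to E17.5.  Three cell types interact:

* **LTin** (lymphoid tissue initiator) cells enter the gut over the window
  and perform an unbiased random walk.  First contact with an LTo cell
  triggers that cell's differentiation.
* **LTo** (lymphoid tissue organiser) cells are stationary stromal cells.
  A differentiated LTo expresses adhesion factors at a level
  `expression in [0, 1]`; each LTi contact increments expression, and past a
  threshold the LTo also emits a chemoattractant.
* **LTi** (lymphoid tissue inducer) cells enter alongside LTin and perform a
  chemokine-biased random walk; their contacts mature LTo expression.

Near a differentiated LTo, motile cells of either kind may **arrest**
(adhesion): per step, with probability `expression * max(0, 1 - d/r_adh)`
against the nearest differentiated LTo.  Arrest is permanent; arrested cells
are the material of the emergent aggregates.  At the end of the window,
single-linkage clusters of arrested cells (linking distance
`patches.linking_distance_um`, minimum size `patches.min_size`) are the
immature PP; the two per-run responses are the patch count and the median
patch area (area = member count x pi r^2, the summed cell footprint).

The domain is a flat rectangle abstracting the opened gut tube: periodic on
the long axis (the tube seam), reflective on the short axis.  The chemokine
field is an instantaneous radial kernel, `expression * max(0, 1 - d/r_chem)`
summed over differentiated LTo whose expression exceeds
`chemokine.threshold`; a static kernel rather than a diffusion PDE keeps the
field a deterministic, cheap function of the LTo states.  An LTi's step
direction is `normalise((1-b) u + b g_hat)` with `u` a uniform random unit
vector, `g_hat` the unit finite-difference gradient, and bias
`b = min(1, local level)`; if the blend cancels numerically the random
direction is used, so every migrating cell moves exactly `speed * dt` per
step.

## Cell input and the E15.5 anchor

The single empirical anchor is that LTin cells occupy 0.45 % of the gut
surface area at E15.5 (t = 24 h).  `e155_count` converts the area fraction
to a cell count, `floor(fraction * area / (pi r_cell^2))`.  Cumulative entry
follows one of three forms — linear (`n t/24`), square-root
(`n sqrt(t/24)`), exponential (`n (e^{kt}-1)/(e^{24k}-1)`,
`k = ln 2/24 h^-1` by default, a doubling per embryonic day) — all equal to
`n` at t = 24 h and extended with their own shape to 72 h, so total input
deliberately differs between forms.  Entry positions are uniform over the
domain (no entry geography is modelled).  LTi cells always enter on the
baseline linear schedule, so the perturbation experiments vary only the
LTin assumption; their anchor fraction defaults to 0.9 % — twice the LTin
anchor — reflecting that the emergent aggregates are predominantly inducer
cells.  An override exists for users who want LTi input to co-vary.

The continuous schedules are integerised by a floor-with-carry accumulator;
a 1e-9 snap before the floor keeps the exact-integer anchor at t = 24 h from
losing a cell to float error.  Over any partition of the window the injected
total equals `floor(cumulative(t_end))` exactly (property-tested).

## Time stepping and determinism

Fixed steps of `dt_minutes` (default 1 min; 4320 steps).  Each step injects
newly arrived cells, moves every migrating cell once, then applies all
LTo updates (differentiation, expression increments) and arrests
synchronously from the step's collected events, all evaluated against the
LTo states at the start of the step.  Because no LTo state changes mid-step,
the outcome is independent of within-step cell ordering, and the engine
updates all cells with array operations.  A run is a pure function of
(configuration, seed); replicate seeds derive from a base seed through
`numpy` `SeedSequence` mixing, recorded per run.

An arresting cell delivers the contact events of its final step (events are
collected before arrests apply) and is inert thereafter.  Only LTin contact
can differentiate an LTo; LTi contact with an undifferentiated LTo does
nothing.  Differentiation is deterministic on first contact.

## Statistical machinery

The Vargha-Delaney A-Test compares a condition's distribution of per-run
responses against the calibrated baseline: the probability that a random
draw from the first sample exceeds one from the second, ties at half weight,
computed from exact integer pair counts.  |A - 0.5| < 0.06 is "no effect";
0.06, 0.14, 0.21 open the small / medium / large bands (large at A >= 0.71
or <= 0.29, the conventional scientific-significance boundaries).  Band
edges are inclusive on the larger-effect side, so A = 0.71 classifies as
large.

Replicate-consistency analysis selects the smallest replicate count n from a
candidate list such that independently seeded same-parameter subsets of n
runs are indistinguishable: all A magnitudes of subsets 2..k against subset
1, on both responses jointly, inside the no-effect band.  When no candidate
passes, the result carries a `None` minimum plus the full score table rather
than raising.

## Calibration

The shipped defaults are this package's own calibration, chosen so the
full-profile baseline forms the 8-12 patches per run reported for the
mouse.  The guiding principle: a counted patch should be a
chemokine-activated aggregation site, not a handful of strays.

* Base expression at differentiation `l0 = 0.05` — a freshly differentiated
  LTo arrests passers-by only weakly, so undeveloped sites do not
  accumulate clusters.
* Expression increment per LTi contact `dl = 0.09`, chemokine threshold
  0.3: three inducer contacts activate attraction, after which capture,
  maturation and arrest reinforce one another and the site grows rapidly.
* Adhesion radius `r_adh = 25 um`: arrested cells concentrate within about
  one linking distance of their LTo, so each site yields one connected
  cluster.
* Chemokine radius `r_chem = 80 um`: attraction basins are local, so
  aggregation sites do not compete for inducer cells across the domain.
* `min_size = 15` with linking distance 20 um: only mature aggregates
  count as patches; late-activating sites fall below the size floor.
* LTo cells: 10 on the full 5000 x 1000 um profile (about one per
  500 x 1000 um of gut strip); nearly all differentiate and activate within
  the window, yielding the murine patch count (median 10 per run over
  seeds, interdecile range 9-10).

Cell geometry and motility (motile radius 5 um, LTo radius 14 um, speed
5 um/min) are in the range reported for embryonic hematopoietic cells and
are configurable; none of them is independently identified by the outputs,
so they are fixed by convention and the behavioural calibration above.

The `test` profile is the same calibration on a 2000 x 500 um strip
(one fifth the area) with three LTo.  It forms ~3 patches per run and runs
in a fraction of a second, which is what makes the multi-hundred-replicate
experiment grids affordable; the full profile is used where the absolute
patch count matters.

## The two assumption experiments

1. **Cell count at E15.5** — the E15.5 fraction is swept over
   0.05-0.45 % in 0.05 % steps (reductions) and the baseline count is
   multiplied 2-5 fold (increases).  At the shipped calibration the patch
   count rises monotonically with the fraction, and the patch-area response
   identifies a robustness window around the anchor: a 0.05 % reduction
   stays inside the A-Test no-effect band, while larger reductions produce
   progressively clearer area effects.  The window this implementation
   computes is one 0.05 %-grid step narrower than the one reported for the
   original simulator (whose calibration is not published); the area
   response here is the sum of a weak activation-timing term (differentiation
   onset scales only with the square root of the cell count under ramped
   entry) and a linear arrested-initiator mass term, which together move the
   response out of the no-effect band between 0.05 % and 0.10 %.
2. **LTin migration rate** — the linear entry schedule is replaced by the
   exponential (slow early, fast late) or square-root (fast early, slow
   late) form, all anchored at E15.5.  Because every exponential through
   the E15.5 anchor delivers a multiple of the linear total by E17.5
   (2.3x at the default growth constant), and because arrested cells of
   both kinds contribute patch mass while entry is spatially uniform, the
   exponential condition in this implementation produces *larger* patches
   (A > 0.5 on area) — total input, not early input, dominates the
   responses here, the opposite direction to the original simulator's
   fewer-and-smaller finding.  The square-root condition, whose total is
   0.58x the linear one, shows the expected small negative effects, and its
   area-effect magnitude is clearly smaller than the exponential's.  This
   directional disagreement is an informative, structural property of the
   model as specified (see Known limitations), not a replication-count
   artefact.

Baseline and perturbed conditions use disjoint seed streams (independent
distributions, no common-random-number pairing), and each experiment table
records n, seeds and the full configuration snapshot.

## Problem sizes

Default experiment replication is 300 runs per condition, the count used
throughout the analysis here; the package's own consistency analysis can
re-derive a sufficient count for any modified calibration.  The test suite
exercises the same pipelines at reduced scale, its own choice of problem
size: 20 full-profile baseline runs for the calibration check, 30-replicate
test-profile grids for effect directions, 100-replicate grids for the
robustness window.

## What the generator does and does not capture

All inputs are synthetic by construction — the simulator is the data
generator.  It captures: stochastic entry and motion, contact-driven
differentiation, cooperative maturation, chemotactic aggregation, and the
resulting run-to-run variability of patch number and size.  It does not
capture: gut growth over the window, 3-D tissue geometry, cell division or
death, volume exclusion among motile cells, detachment, multiple chemokine
species, or spatially structured cell entry.  Passing tests therefore speak
to the internal logic and robustness of the modelled mechanism, not to
quantitative agreement with any particular wet-lab measurement beyond the
anchored E15.5 density and the 8-12 murine patch range.

## Numerical choices and degenerate inputs

* Wrapped metric: periodic minimal-image x distance, plain y distance;
  patch centroids unwrap around a member before averaging.
* Chemokine gradient: central differences with step `fd_step` (1 um); the
  gradient at a source centre vanishes by symmetry.
* A-Test: exact integer counting (`searchsorted` twice), one final
  division; `classify_effect` snaps |A - 0.5| at 1e-12 so printed-precision
  thresholds are inclusive.
* Median of an even-length list: mean of the two central values; a run with
  no patches reports median area 0, so every run contributes to the
  comparison distributions.
* LTo placement: uniform rejection sampling, overlap-free; infeasible
  requests fail with the attempt count after `1000 + 200 n` draws.
* Degenerate conditions (zero fraction, no LTo, no sources) short-circuit
  to well-defined empty results rather than erroring.

## Known limitations

Two behaviours of the published analysis are not reproduced by this
re-implementation, and the cause is structural rather than statistical
(verified over a wide range of calibrations at up to 1000 replicates per
condition):

* **Entry-schedule direction.** Patch count and area here track the total
  LTin input.  Any exponential cumulative anchored to the E15.5 count
  exceeds the linear total by E17.5, cells enter uniformly over the domain,
  and arrested initiator cells count toward patch mass — so the late
  surplus inflates the aggregates and the exponential condition scores
  A > 0.5 instead of the original's A < 0.5.  Reproducing "fewer, smaller"
  would require early-input dominance: input that stops aggregating late,
  spatially peripheral entry, or patch mass that excludes initiator cells —
  all outside this model's rules.
* **Robustness-window width.** The no-effect window for reductions of the
  E15.5 fraction comes out at 0.05 % rather than 0.10 %: with
  differentiation deterministic on first contact, the only nonlinear
  response channel is activation timing, which is too weak (square-root in
  the count) to keep a 22 % cell-count reduction strictly inside the
  no-effect band while pushing a 33 % reduction out of it.


* The calibration is behavioural, not mechanistic: parameter values were
  selected for the emergent patch statistics, and other parameter sets can
  produce the same statistics (the responses identify only a few effective
  combinations).
* Patch area as summed footprint undercounts spread-out aggregates relative
  to a hull-based measure; comparisons between conditions are unaffected
  because the same measure is applied everywhere.
* The per-step arrest probability is dt-dependent; changing `dt_minutes`
  rescales effective adhesion and requires recalibration.
* A-Test comparisons at small replicate counts are noisy (sd of A under no
  effect is about `sqrt((n1+n2+1)/(12 n1 n2))`, roughly 0.04 at n = 100);
  window boundaries quoted at 0.05 %-grid resolution inherit that noise.
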