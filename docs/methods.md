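# Methods

`gonadsim` models the *C. elegans* hermaphrodite gonadal arm as a
self-renewing cell factory and asks how the spatial profile of germ-cell
cycle lengths trades off replication-dependent mutation accumulation against
the speed of development and reproduction.  This note documents the model,
its assumptions, the calibrated constants, the numerical choices, and what
the synthetic-data tests do and do not demonstrate.

## The lattice model of the mitotic zone

The mitotic zone (MZ) is a cylindrical lattice: `length` rows along the
distal–proximal axis, each row a circular ring of `width` slots (the short
axis wraps, mimicking the tube-like gonad).  At most one cell occupies a
slot.  A single primordial cell seeds the distal end; divisions fill the
lattice width-first, then length-wise.

When a cell divides, one daughter keeps the parent's slot and the other is
placed by three rules applied in order:

1. if the division row has an empty slot, cells shift along the circular
   short axis so the nearest empty slot is filled (equidistant empty slots
   are tie-broken by one RNG draw);
2. otherwise, if the next (more proximal) row has an empty slot, the
   daughter is pushed forward into it, rearranging that row the same way;
3. otherwise the daughter is pushed forward or sideways with probability 1/2
   each (forward only in single-slot rows), displacing the occupant, and the
   displaced cell re-enters the same rules until an empty slot fills or a
   cell is pushed past the last row — out of the MZ and into the meiotic
   zone.  At a full last row the same coin applies; a forward outcome exits
   the walking cell.  (We benchmarked the alternative reading — exit
   immediately at the last row — and it reproduces the flat-profile
   benchmark optima much less well; see the repository history.)

Cell-cycle length is a piecewise-linear function of row and of the
*developmental clock*, which is the cumulative division count rather than
wall-clock time: this makes every simulation input except the reproductive
schedule invariant under a global rescaling of cycling speed, so
pedigree-depth results are non-dimensional in absolute cycle length.
Division waiting times are uniform with mean equal to the local cycle length
and width 1 % of it, drawn independently per daughter; a cell pushed to a
different row has its pending division time rescaled by the ratio of the new
and old rows' cycle lengths.  Events are processed in time order; exact ties
resolve to the earlier-born cell.

Two dynamical properties of this model are worth knowing:

* **Eviction loss.** A cell pushed out of the MZ abandons its cycle in
  progress, so the steady-state division rate is noticeably below
  `N/tau` (about `N ln2 / tau` when desynchronized, lower when
  synchronized).
* **Division synchrony.** With a spatially flat profile and 1 % jitter, the
  population stays division-synchronized for many generations (cohorts
  divide in bursts ~one cycle apart).  Spatial gradients desynchronize the
  population through the row-change rescaling.

Both properties shape the developmental-timing calibration below.

## Pedigree depth and mutation-model variants

The pedigree depth of a cell is the number of divisions separating it from
the primordial cell; the mean depth of an organ's differentiated cells is
proportional to its mean replication-dependent mutation load, and is bounded
below by `log2(n)` for `n` cells (balanced binary tree).  Variants:

* **standard** — both daughters inherit parent + 1;
* **immortal strand** — a parent in the distal-most row keeps its template
  strands: the staying daughter inherits + 0 and the pushed daughter + 2
  (once row 1 is full, one daughter is always displaced from it).  Away from
  row 1 the variant falls back to + 1;
* **rate-scaled** — mutation accrual inversely proportional to cycling
  speed: both daughters inherit + 1/γ, γ = parent's cycle length over the
  minimum cycle length in the MZ.

## Meiotic zone, fates, and the reproductive schedule

Cells leaving the MZ enter the meiotic zone (MeZ), a first-in-first-out
queue.  The first 44 entrants are drawn as primary spermatocytes (exempt
from apoptosis).  Afterwards cells mature as oocytes from the proximal end;
each popped cell first survives an apoptosis draw whose probability depends
on its MZ-exit sequence index (stage-wise bands rising from 68 % to 99 % —
keyed to the division clock, not elapsed time, so faster cycling cannot
"outrun" apoptosis).

Oocyte maturation is demand-driven and supply-gated: oocytes are demanded on
the experimentally measured reproductive schedule (44 spermatocytes during
larval development, then 23/83/64/5/1 oocytes in successive 24 h windows),
and a demand can only be served once the MeZ has filled to its
stage-interpolated size (500 cells at L4, 749 at L4+1 d, 1077 at L4+3 d) —
oocyte growth requires a minimal gonad because meiotic cells stream
cytoplasm into oocytes.  Fast-cycling germ lines therefore reproduce on the
measured schedule, while slow-cycling ones delay reproduction until the MeZ
has grown.  A pure size-overflow efflux (release whenever occupancy exceeds
the interpolated size) is inconsistent with the apoptosis and schedule
tables jointly — it would release several-fold more oocytes in the first
adult day than are observed — but it *is* the right bookkeeping for
calibrating the apoptosis profile from the influx/efflux balance, and
`optimization_engine.calibrate_apoptosis` uses it for exactly that purpose.

Progeny birth times equal oocyte maturation times; egg laying precedes the
onset of germ-line proliferation by 24 h (mid-L4 is reached 54 h after egg
laying), and embryonic/larval development is assumed to proceed at constant
speed.  The averaged schedule over replicate runs is binned into 1 h age
classes and assembled into a Leslie matrix whose birth row is placed so the
characteristic equation is the Euler–Lotka relation `sum_a m_a λ^-a = 1`
(verified against closed forms; halving the age step changes r by < 1 %).
The growth rate is `r = ln(dominant eigenvalue)` and fitness combines growth
and mutation load as `1 + s_U + s_G` with `s_U = −U (p−p0)/(2 p0)` (selfing)
and `ln(1+s_G) = (r−r0)/r0 · ln N`, `N` the total progeny of the schedule.
One gonadal arm is modeled throughout, so `N = 176`.

## Developmental-timing calibration

Stage anchors are defined on the division clock (L4 = 400, L4+1 = 1200,
L4+3 = 2400 cumulative divisions) and parameterize the cycle profile,
geometry, and MeZ size interpolation.  The *constraints* that enforce the
observed speed of development — minimum divisions by 30/54/102 h and the
spermatogenesis deadline — cannot be taken as external measurements: they
are only defined relative to a simulator, because the division count is not
directly observable.  We therefore calibrate them in-simulator, as the
original analysis did: `synthetic_data.calibrate_stage_clocks` runs the
reference experimental-speed profile (flat 3.4 h early cycles developing
into a ~2-fold distal–proximal gradient on the cone-shaped ~256-cell organ)
and reads off the divisions reached at the measured stage times, giving
checkpoints of 255/1236/2753 divisions by 30/54/102 h and a spermatogenesis
deadline of 31.3 h.  The reference conditions are exactly feasible under
these constraints by construction.  (The division-synchrony quantization
described above is why a fixed literal like "400 divisions by 30 h" is
unattainable for *any* profile bounded by the 3.4 h early-larval speed limit
in this simulator: generation 9 of a synchronized single-seed fill lands at
30.6 h.)

## Optimization

`grid_search` minimizes the empirical mean objective (replicates per point:
450 full-protocol, 50 at desk scale, 100 in the reproduction script) over a
parameter grid — geometry (integer length/width) and stage-wise distal cycle
lengths, with the proximal end pinned at the 2.8 h speed limit and pre-L4
cycling spatially flat — then self-refines around the best decile with
halved steps.  Feasibility requires every constraint margin nonnegative on
average.  `mcmc_posterior` is a threshold-acceptance Metropolis chain:
Gaussian proposals per parameter (integer parameters move on the integer
lattice, reflected at bounds), rejection when the empirical objective
exceeds the grid optimum by ε (0.01 for fitness, 0.1 otherwise) or a
constraint function is violated by more than its ε (0.1 for division-count
"cell production" checkpoints, 1.0 for gamete-count "fecundity" windows);
burn-in is the lag at which every parameter's autocorrelation has decayed to
1/e, and the posterior keeps post-burn-in samples that meet the constraints
and do at least as well as the start (2.5/97.5 percentiles give credible
intervals).

## EdU pulse-chase simulation and fitting

Pulse-chase runs start from a pre-filled MZ whose cell ages follow the
asynchronous exponential density `f` with `f(0) = 2 f(1)`; phase boundaries
come from fixed relative phase lengths (G1/S/G2/M), obtained from measured
phase indices by inverting `F(x) = 2 − 2^(1−x)`.  After a 2 h pre-run,
S-phase cells are marked EdU-positive (the 15–30 min feeding pulse is
idealized as instantaneous), and per-cell snapshots (row, phase, DNA content
ramping linearly 2C→4C across S, EdU flag) are taken at chase times of
0–8 h.  Cycle parameters are constant over a run.

Fitting compares data to simulations of the same experiment over a grid of
control-point cycle lengths (two spatial control points: distal end and
proximal end of the fitted region; 2.8–11.2 h in 0.2 h steps by default) by
two metrics: DEMD (count-weighted circular earth mover's distances between
DNA-content histograms partitioned by chase × compartment × EdU status) and
FLM (count-weighted squared differences of labeled-mitoses fractions).  The
DNA axis [1.6 C, 4.4 C] maps onto a 32-bin circle so that division adjacency
(4C→2C) is a short hop while the 2C and 4C peaks stay distinct; the circular
EMD is computed exactly via the median-offset cumulative-sum formula and is
a true metric (property-tested, and verified against a min-cost-flow LP).
Ties in the grid argmin resolve to the smallest distal length.  The reported
summary is the ratio of fitted control-point lengths (distal / proximal),
i.e. the DMMZ/MMZ cycle-*speed* ratio.

Two methodological points:

* **Measurement model.** Simulated arms are passed through the same
  measurement model as the data before histogramming: multiplicative
  lognormal intensity noise at the assay's measurement CV (a `FitSpec`
  parameter, assumed calibrated outside the fit, e.g. from control-peak
  widths) followed by the same per-arm 10 %/85 % quantile renormalization to
  2C/4C.  Comparing sharp theoretical histograms against smeared data biases
  the EMD argmin toward slower distal cycling by about one grid step;
  mirroring the measurement model removes that bias.
* **Bootstrap.** Confidence intervals resample gonadal arms with
  replacement, independently within each chase-time stratum (so every
  replicate keeps the same number of arms per chase).  The simulated grid is
  computed once and shared across bootstrap replicates; 60 simulated arms
  per grid point keep the frozen simulation-side sampling noise small
  relative to the data side (important for FLM, which only uses the ~3 % of
  cells in M phase).

### Pre-meiotic arrest

In simulations that include the proximal MZ, a cell entering G2 there
arrests (leaves the mitotic cycle, retaining G2 DNA content, and keeps
occupying its lattice slot) whenever the simulated local mitotic index
exceeds the experimentally derived index at its row.  The row-by-row
experimental index profile is not reproduced here; a synthetic stand-in
(no arrest distal of the PMZ, a low M-phase ceiling within it) is provided
for the corresponding presets.

## The synthetic-data generator

`synthetic_data.generate_pulse_chase` emulates the measured per-cell tables
of a pulse-chase experiment: one simulated arm per (chase time, replicate),
default 20 arms per chase at chases {0,1,2,3,5,6,8} h on the 11-row
DMMZ+MMZ region of the cone-shaped stand-in geometry, ground-truth gradient
4.2 h → 2.8 h (distal/proximal speed ratio 1.50).  Measurement noise:
multiplicative lognormal DNA intensity noise (default CV 10 %), EdU
misclassification (default 2 %), per-arm quantile renormalization.
Biological arm-to-arm variability: each arm's cycle lengths are scaled by a
lognormal factor with CV 5 % (worm staging/growth spread) — this is what
gives the arm bootstrap nonzero width; the spatial ratio is unaffected.

What the generator does *not* emulate: image segmentation errors, the
depth-dependent fluorescence attenuation of real confocal stacks (and the
"top layer" selection used to avoid it), spatial noise in row assignment,
and any arm-level covariance between noise and biology.  Synthetic-recovery
results therefore demonstrate that the estimators are consistent and
calibrated under the stated measurement model, not that real-microscopy
systematics are harmless.

## Fixture tables and stand-ins

In-code fixtures: the stage-wise apoptosis probabilities (68/83/86/98/99 %
on exit-index bands 1–210/211–682/683–1150/1151–1478/1479+), the
reproductive schedule and calibrated development checkpoints, MeZ size
anchors, DMMZ/MMZ boundaries (rows 1–8/9–15 at L4; 1–6/7–11 at L4+1 d),
speed limits (3.4 h pre-L4, 2.8 h after), and a cone-like stand-in geometry
(19 rows, widths tapering 12→15, mean 13.5, ~256 cells) matching the printed
mean organ dimensions — the row-by-row measured geometry is not reproduced.

## Known limitations

* The displacement micro-rules leave ~1 % ambiguity relative to the original
  implementation: single-row benchmark optima come out 0.1–0.2 divisions
  low.
* Production-constraint literals are simulator-calibrated (see above);
  absolute division counts at stage boundaries are not comparable across
  implementations.
* The pre-meiotic-arrest pathway and the experimental-geometry presets run
  against synthetic stand-in profiles, so their outputs are qualitative.
* Posterior credible intervals from the threshold-acceptance chain describe
  the near-optimal sublevel set, not a Bayesian posterior in the usual
  sense.
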