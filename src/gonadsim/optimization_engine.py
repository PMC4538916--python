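"""Optimization of MZ geometry and cell-cycle profiles under reproduction
constraints: self-refining grid search, threshold-acceptance MCMC posteriors,
and calibration of the apoptosis profile.

Free parameters (a dict) can include:

* ``length``, ``width`` — lattice dimensions (integers);
* ``flat`` — one cycle length fixed in space and time;
* ``v_pre`` — the spatially flat pre-L4 cycle length;
* ``d_L4``, ``d_L4p1``, ``d_L4p3`` — distal-end cycle lengths at the L4,
  L4+1 d, and L4+3 d stage anchors (the proximal end is pinned at the 2.8 h
  speed limit; pre-L4 everything is pinned at ``v_pre``, default the 3.4 h
  early-larval limit).

Objectives are empirical averages over replicate stochastic simulations:
mean pedigree depth of the first n cells leaving the MZ, mean pedigree depth
of gamete-fated cells, or the growth/mutation-load fitness (maximized by
minimizing its negative).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .fitness_growth import FitnessParams, ReproductiveSchedule, fitness, growth_rate
from .lattice_simulator import SimulationConfig, run_mutation_accumulation
from .pedigree_analysis import average_pedigree_depth
from .profiles import CellCycleProfile, MZGeometry
from .schedules import ApoptosisProfile, MeioticQueue, ProductionSchedule
from .synthetic_data import EGG_TO_ONSET_H, SPEED_LIMITS, STAGE_CLOCKS, load_fixtures

__all__ = [
    "OptimizationProblem",
    "OptimizationResult",
    "EvalResult",
    "build_geometry_profile",
    "evaluate_objective",
    "grid_search",
    "mcmc_posterior",
    "calibrate_apoptosis",
    "preset",
    "PRESETS",
]

INTEGER_PARAMS = {"length", "width"}
STAGE_PARAM_ANCHORS = (
    ("v_pre", 0.0),
    ("d_L4", STAGE_CLOCKS["L4"][0]),
    ("d_L4p1", STAGE_CLOCKS["L4+1"][0]),
    ("d_L4p3", STAGE_CLOCKS["L4+3"][0]),
)


@dataclass(frozen=True)
class OptimizationProblem:
    """One optimization setup (a Table-1-style row).

    ``objective``: "first_n" | "gametes" | "fitness".
    Constraint fields are optional; ``production=True`` enforces the gamete
    schedule windows and the division checkpoints.
    """

    objective: str = "first_n"
    first_n: int = 3000
    free: tuple[str, ...] = ("length", "width")
    bounds: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    max_mz_cells: int | None = None
    exact_mz_cells: int | None = None
    max_length: int | None = None
    max_width: int | None = None
    production: bool = False
    use_apoptosis: bool = False
    variant: str = "standard"
    premeiosis: bool = False
    geometry_override: MZGeometry | None = None
    replicates: int = 450
    proximal_post: float = SPEED_LIMITS["post_L4"]
    proximal_pre: float = SPEED_LIMITS["pre_L4"]
    U: float = 0.03
    reference: tuple[float, float, float] | None = None  # (p0, r0, N)

    def default_bounds(self, name: str) -> tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        if name == "length":
            return (1, self.max_length or 2000)
        if name == "width":
            return (1, self.max_width or 2000)
        if name == "v_pre":
            return (self.proximal_pre, 32.0)
        return (self.proximal_post, 32.0)


@dataclass
class EvalResult:
    value: float
    se: float
    margins: dict
    feasible: bool
    extra: dict = field(default_factory=dict)


@dataclass
class OptimizationResult:
    best_params: dict
    best_value: float
    best_se: float
    margins: dict
    feasible: bool
    history: list
    posterior: np.ndarray | None = None
    posterior_params: list | None = None
    credible_intervals: dict | None = None


def build_geometry_profile(
    problem: OptimizationProblem, params: dict
) -> tuple[MZGeometry, CellCycleProfile]:
    """Materialize the lattice and cycle profile for one parameter point."""
    p = {**problem.fixed, **params}
    if problem.geometry_override is not None:
        geometry = problem.geometry_override
    else:
        geometry = MZGeometry.rectangular(int(p["length"]), int(p["width"]))
    n_rows = geometry.n_rows

    if "flat" in p:
        profile = CellCycleProfile.flat(float(p["flat"]))
    elif "flat_limits" in p:
        # spatially flat at the stage speed limits: 3.4 h before L4, 2.8 after
        profile = CellCycleProfile.flat(
            problem.proximal_post,
            min_cycle_length=problem.proximal_post,
            anchors=(0.0, STAGE_CLOCKS["L4"][0]),
            lengths_by_anchor=(problem.proximal_pre, problem.proximal_post),
        )
    else:
        v_pre = float(p.get("v_pre", problem.proximal_pre))
        anchors, dist, prox = [0.0], [v_pre], [v_pre]
        for name, clk in STAGE_PARAM_ANCHORS[1:]:
            if name in p:
                anchors.append(float(clk))
                dist.append(float(p[name]))
                prox.append(problem.proximal_post)
        if len(anchors) == 1:
            raise ValueError("no stage cycle-length parameters given")
        profile = CellCycleProfile(
            control_rows=(1, n_rows) if n_rows > 1 else (1,),
            anchors=tuple(anchors),
            lengths=tuple((d, x) if n_rows > 1 else (d,) for d, x in zip(dist, prox)),
            min_cycle_length=min(problem.proximal_post, problem.proximal_pre),
        )
    return geometry, profile


def _geometry_ok(problem: OptimizationProblem, params: dict) -> bool:
    p = {**problem.fixed, **params}
    if problem.geometry_override is not None:
        return True
    length, width = int(p["length"]), int(p["width"])
    if length < 1 or width < 1:
        return False
    cells = length * width
    if problem.exact_mz_cells is not None and cells != problem.exact_mz_cells:
        return False
    if problem.max_mz_cells is not None and cells > problem.max_mz_cells:
        return False
    if problem.max_length is not None and length > problem.max_length:
        return False
    if problem.max_width is not None and width > problem.max_width:
        return False
    return True


_REFERENCE_CACHE: dict = {}


def fitness_reference(
    problem: OptimizationProblem, replicates: int = 60, seed: int = 9001
) -> tuple[float, float, float]:
    """(p0, r0, N) baseline for the fitness objective: the same organ cycling
    spatially flat at the stage speed limits.  Cached per geometry."""
    geometry = (problem.geometry_override
                or MZGeometry.rectangular(int(problem.fixed.get("length", 19)),
                                          int(problem.fixed.get("width", 12))))
    key = geometry.row_capacities
    if key in _REFERENCE_CACHE:
        return _REFERENCE_CACHE[key]
    ref_problem = OptimizationProblem(
        objective="gametes", production=True, geometry_override=geometry,
        fixed={"flat_limits": 1}, replicates=replicates,
    )
    fx = load_fixtures()
    depths = []
    oocyte_times = []
    for k in range(replicates):
        cfg = SimulationConfig(seed=(seed + k) & 0x7FFFFFFF)
        geo, prof = build_geometry_profile(ref_problem, {})
        res = run_mutation_accumulation(cfg, geo, prof, apoptosis=fx.apoptosis,
                                        schedule=fx.schedule, queue=fx.meiotic_queue,
                                        n_exits=3000)
        depths.append(average_pedigree_depth(res, "gametes"))
        oocyte_times.append(res.oocyte_times_h)
    sched = ReproductiveSchedule.averaged(oocyte_times, offset_h=EGG_TO_ONSET_H)
    out = (float(np.mean(depths)), growth_rate(sched), sched.total_progeny)
    _REFERENCE_CACHE[key] = out
    return out


def evaluate_objective(
    problem: OptimizationProblem,
    params: dict,
    replicates: int | None = None,
    seed: int = 0,
) -> EvalResult:
    """Empirical mean of the objective plus per-constraint margins.

    Margins are >= 0 when satisfied: division-checkpoint margins are
    (divisions done - required) at each checkpoint hour, production margins
    are (gametes released - scheduled) at each window end.
    """
    reps = problem.replicates if replicates is None else replicates
    if not _geometry_ok(problem, params):
        return EvalResult(math.inf, 0.0, {}, False, {"reason": "geometry"})
    geometry, profile = build_geometry_profile(problem, params)
    fx = load_fixtures()
    apoptosis = fx.apoptosis if (problem.use_apoptosis or problem.production) else None
    schedule = fx.schedule if problem.production else None
    queue = fx.meiotic_queue if problem.production else None

    n_exits = problem.first_n if problem.objective == "first_n" else 3000
    vals = np.empty(reps)
    margin_acc: dict[str, list] = {}
    oocyte_times_all: list[np.ndarray] = []
    mi_profile = None
    if problem.premeiosis:
        # synthetic stand-in PMZ mitotic-index profile: no pre-meiotic entry
        # distal of the PMZ, a low M-phase ceiling within it
        n_rows = geometry.n_rows
        pmz0 = int(0.6 * n_rows)
        mi_profile = tuple(
            [np.inf] * pmz0 + [0.02] * (n_rows - pmz0)
        )

    for k in range(reps):
        cfg = SimulationConfig(
            seed=(seed * 69069 + k * 1013904223 + 7) & 0x7FFFFFFF,
            pedigree_variant=problem.variant,
            premeiosis=problem.premeiosis,
            mitotic_index_profile=mi_profile,
        )
        res = run_mutation_accumulation(
            cfg, geometry, profile, apoptosis=apoptosis, schedule=schedule,
            queue=queue, n_exits=n_exits,
        )
        if problem.objective == "first_n":
            if res.n_exits < problem.first_n:
                return EvalResult(math.inf, 0.0, {}, False, {"reason": "too few exits"})
            vals[k] = average_pedigree_depth(res, ("first_n", problem.first_n))
        else:
            try:
                depth = average_pedigree_depth(res, "gametes")
            except ValueError:
                return EvalResult(math.inf, 0.0, {}, False, {"reason": "no gametes"})
            if problem.objective == "gametes":
                vals[k] = depth
            else:  # fitness (maximized): store depth now, growth handled below
                vals[k] = depth
                oocyte_times_all.append(res.oocyte_times_h)

        if problem.production:
            for (t_h, req) in schedule.checkpoints:
                margin_acc.setdefault(f"divisions@{t_h:g}h", []).append(
                    res.clock_at(t_h) - req
                )
            t_sperm = max(w.t_end_h for w in schedule.windows if w.gamete == "sperm")
            n_sperm = int((res.sperm_times_h <= t_sperm + 1e-9).sum())
            margin_acc.setdefault(f"sperm@{t_sperm:g}h", []).append(
                n_sperm - schedule.sperm_target
            )
            cum = 0
            for w in schedule.windows:
                if w.gamete != "oocyte":
                    continue
                cum += w.count
                got = int((res.oocyte_times_h <= w.t_end_h + 1e-9).sum())
                margin_acc.setdefault(f"oocytes@{w.t_end_h:g}h", []).append(got - cum)

    margins = {k: float(np.mean(v)) for k, v in margin_acc.items()}
    feasible = all(m >= 0 for m in margins.values())
    extra: dict = {}

    if problem.objective == "fitness":
        p0, r0, n_ref = problem.reference or fitness_reference(problem)
        sched = ReproductiveSchedule.averaged(oocyte_times_all, offset_h=EGG_TO_ONSET_H)
        r = growth_rate(sched)
        p_mean = float(vals.mean())
        fit = fitness(FitnessParams(U=problem.U, p0=p0, r0=r0, p=p_mean, r=r,
                                    N=sched.total_progeny or n_ref))
        extra = {"pedigree_depth": p_mean, "growth_rate": r, "fitness": fit}
        return EvalResult(-fit, float(vals.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0,
                          margins, feasible, extra)

    se = float(vals.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return EvalResult(float(vals.mean()), se, margins, feasible, extra)


def _grid_points(grid: dict) -> list[dict]:
    names = list(grid)
    return [dict(zip(names, combo)) for combo in itertools.product(*(grid[n] for n in names))]


def grid_search(
    problem: OptimizationProblem,
    grid: dict,
    refinement_levels: int = 2,
    replicates: int | None = None,
    seed: int = 0,
    objective_fn=None,
) -> OptimizationResult:
    """Evaluate a parameter grid and self-refine around the best decile.

    ``grid`` maps parameter names to value arrays.  At each refinement level
    the axis-aligned bounding box of the best-decile feasible points is
    re-gridded with halved steps.  ``objective_fn(params) -> EvalResult`` may
    replace the simulation objective (used by the unit tests).
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be nonempty")
    fn = objective_fn or (
        lambda prm, s: evaluate_objective(problem, prm, replicates=replicates, seed=s)
    )
    history = []
    points = _grid_points(grid)
    axes = {n: np.sort(np.unique(np.asarray(v, dtype=float))) for n, v in grid.items()}
    for level in range(refinement_levels + 1):
        for prm in points:
            if any(h["params"] == prm for h in history):
                continue
            ev = fn(prm, seed + 131 * level)
            history.append({"params": prm, "eval": ev, "level": level})
        feas = [h for h in history if h["eval"].feasible and np.isfinite(h["eval"].value)]
        if not feas:
            return OptimizationResult({}, math.inf, 0.0, {}, False, history)
        feas.sort(key=lambda h: h["eval"].value)
        if level == refinement_levels:
            break
        # refine around the best decile (at least one point): coordinate-wise
        # midpoint moves toward each axis neighbour — halved local steps
        # without a cartesian candidate explosion
        top = feas[: max(1, len(feas) // 10)]
        new_points = []
        for h in top:
            for n in grid:
                axis = axes[n]
                b_lo, b_hi = problem.default_bounds(n)
                v = float(h["params"][n])
                i = int(np.searchsorted(axis, v))
                moves = []
                if i > 0:
                    moves.append((v + axis[i - 1]) / 2.0)
                if i < axis.size - 1:
                    moves.append((v + axis[min(i + 1, axis.size - 1)]) / 2.0)
                for m in moves:
                    m = float(np.clip(m, b_lo, b_hi))
                    if n in INTEGER_PARAMS:
                        m = int(round(m))
                    else:
                        m = round(m, 6)
                    if m == h["params"][n]:
                        continue
                    cand = {**h["params"], n: m}
                    if cand not in new_points:
                        new_points.append(cand)
                    axes[n] = np.sort(np.unique(np.append(axes[n], float(m))))
        points = new_points
    best = feas[0]
    return OptimizationResult(
        best_params=best["params"],
        best_value=best["eval"].value,
        best_se=best["eval"].se,
        margins=best["eval"].margins,
        feasible=True,
        history=history,
    )


def _autocorr_burnin(samples: np.ndarray, threshold: float = 1.0 / np.e) -> int:
    """Smallest lag at which every parameter's |autocorrelation| has decayed
    to the threshold, estimated on the whole chain."""
    n, d = samples.shape
    burn = 0
    for j in range(d):
        x = samples[:, j] - samples[:, j].mean()
        var = float(x @ x)
        if var <= 0:
            continue
        lag = 0
        for lag in range(1, n):
            ac = float(x[:-lag] @ x[lag:]) / var
            if abs(ac) <= threshold:
                break
        burn = max(burn, lag)
    return burn


def mcmc_posterior(
    problem: OptimizationProblem,
    start_params: dict,
    start_value: float,
    start_margins: dict | None = None,
    iterations: int = 10_000,
    replicates: int | None = None,
    seed: int = 0,
    proposal_scales: dict | None = None,
    eps_objective: float = 0.1,
    eps_production: float = 0.1,
    eps_fecundity: float = 1.0,
    eps_fitness: float = 0.01,
    objective_fn=None,
) -> OptimizationResult:
    """Threshold-acceptance Metropolis chain around a grid-search optimum.

    A proposed move is rejected if its empirical objective average exceeds the
    grid optimum by more than epsilon (0.01 for the fitness metric, 0.1
    otherwise) or if a constraint margin falls more than its epsilon below
    the optimum's margin (0.1 for division-count "cell production"
    checkpoints, 1.0 for gamete-count "fecundity" windows); otherwise it is
    accepted, so the chain explores the near-optimal sublevel set.  Burn-in
    is set post hoc at the lag where every parameter's autocorrelation has
    decayed to 1/e; the posterior keeps post-burn-in samples that satisfy the
    constraints and do at least as well as the start.
    """
    rng = np.random.default_rng(seed)
    fn = objective_fn or (
        lambda prm, s: evaluate_objective(problem, prm, replicates=replicates, seed=s)
    )
    names = sorted(start_params)
    eps_obj = eps_fitness if problem.objective == "fitness" else eps_objective
    scales = proposal_scales or {}
    ref_margins = start_margins or {}

    def margin_eps(key: str) -> float:
        return eps_production if key.startswith("divisions") else eps_fecundity

    cur = dict(start_params)
    chain = [dict(cur)]  # the (feasible) grid optimum seeds the chain
    evals = [start_value]
    for it in range(iterations):
        prop = {}
        for n in names:
            sc = scales.get(n, 1.0)
            v = cur[n] + rng.normal(0.0, sc)
            lo, hi = problem.default_bounds(n)
            # reflect at the bounds
            while v < lo or v > hi:
                if v < lo:
                    v = 2 * lo - v
                else:
                    v = 2 * hi - v
            if n in INTEGER_PARAMS:
                v = int(round(v))
            prop[n] = v
        ev = fn(prop, int(rng.integers(0, 2**31 - 1)))
        ok = np.isfinite(ev.value) and ev.value <= start_value + eps_obj
        if ok:
            for key in ref_margins:
                # constraint function violated by more than its epsilon
                if ev.margins.get(key, -math.inf) < -margin_eps(key):
                    ok = False
                    break
        if ok:
            cur = prop
            cur_ev = ev
        else:
            cur_ev = None
        chain.append(dict(cur))
        evals.append(cur_ev.value if cur_ev is not None else (evals[-1] if evals else start_value))

    arr = np.array([[c[n] for n in names] for c in chain], dtype=float)
    vals = np.asarray(evals)
    burn = _autocorr_burnin(arr)
    keep = vals[burn:] <= start_value + 1e-12
    post = arr[burn:][keep]
    if post.size == 0:
        # nothing strictly as good as the start survived thresholding: the
        # posterior collapses to the starting optimum
        post = np.array([[start_params[n] for n in names]], dtype=float)
    ci = {
        n: (float(np.percentile(post[:, j], 2.5)), float(np.percentile(post[:, j], 97.5)))
        for j, n in enumerate(names)
    }
    return OptimizationResult(
        best_params=dict(start_params),
        best_value=start_value,
        best_se=0.0,
        margins=ref_margins,
        feasible=True,
        history=[],
        posterior=post,
        posterior_params=names,
        credible_intervals=ci,
    )


def _overflow_pops(exit_time: np.ndarray, exit_clock: np.ndarray,
                   queue: MeioticQueue, sperm: int = 44) -> np.ndarray:
    """Cumulative number of post-sperm cells popped from the MeZ by each exit
    event, under pure size-overflow efflux (the influx-minus-size accounting
    used to calibrate apoptosis)."""
    n = len(exit_time)
    popped = np.zeros(n)
    cur = 0.0
    for i in range(n):
        entries = i + 1 - sperm
        cap = queue.capacity(exit_clock[i])
        cur = max(cur, entries - cap)
        popped[i] = max(cur, 0.0)
    return popped


def calibrate_apoptosis(
    target_schedule: ProductionSchedule,
    geometry: MZGeometry,
    profile: CellCycleProfile,
    queue: MeioticQueue,
    seed: int = 0,
    replicates: int = 5,
) -> ApoptosisProfile:
    """Stage-wise apoptosis probabilities from the influx/efflux balance.

    Simulates the MZ under the given profile, computes the MeZ leaver flux in
    each oocyte window as (distal influx) minus (MeZ size change), and sets
    the window's apoptosis probability so the surviving efflux matches the
    scheduled oocyte count: p_k = 1 - demand_k / leavers_k.  Index
    breakpoints are placed at the exit indices popped at the window edges;
    primary spermatocytes are exempt by construction.
    """
    demands = [w for w in target_schedule.windows if w.gamete == "oocyte"]
    ends = [w.t_end_h for w in demands]
    pops_at_end = np.zeros((replicates, len(ends)))
    for k in range(replicates):
        cfg = SimulationConfig(seed=(seed * 7907 + k) & 0x7FFFFFFF)
        # extend the run until the exit stream covers the last window
        n_exits = 4000
        while True:
            res = run_mutation_accumulation(cfg, geometry, profile, n_exits=n_exits)
            if (res.n_exits < n_exits
                    or res.exits["exit_time_h"].iloc[-1] >= ends[-1]
                    or n_exits >= 32000):
                break
            n_exits *= 2
        et = res.exits["exit_time_h"].to_numpy()
        ec = res.exits["exit_clock"].to_numpy()
        popped = _overflow_pops(et, ec, queue)
        for j, te in enumerate(ends):
            i = int(np.searchsorted(et, te, side="right"))
            pops_at_end[k, j] = popped[i - 1] if i > 0 else 0.0
    mean_pops = pops_at_end.mean(axis=0)
    probs: list[float] = []
    breakpoints: list[int] = []
    prev = 0.0
    for j, w in enumerate(demands):
        leavers = mean_pops[j] - prev
        if leavers <= 0:
            raise ValueError(
                f"no MeZ efflux in window ending {w.t_end_h} h: schedule unattainable"
            )
        p = 1.0 - min(w.count / leavers, 1.0)
        probs.append(float(p))
        if j < len(demands) - 1:
            breakpoints.append(int(round(44 + mean_pops[j])))
        prev = mean_pops[j]
    # collapse duplicate breakpoints (possible when windows see no efflux)
    bps, ps = [], [probs[0]]
    for b, p in zip(breakpoints, probs[1:]):
        if bps and b <= bps[-1]:
            continue
        bps.append(b)
        ps.append(p)
    return ApoptosisProfile(tuple(bps), tuple(ps))


def _desk(values, full_values=None):
    return values


PRESETS: dict[str, dict] = {
    # Table-1-style setups.  "grid" entries are desk-scale search grids:
    # cartesian products over the free parameters, infeasible geometry
    # combinations filtered by the problem's constraints.  Printed optimal
    # shapes from the study are included as candidate grid values.
    "opt1": {
        "problem": dict(objective="first_n", free=("length", "width", "v_pre",
                                                   "d_L4", "d_L4p1", "d_L4p3"),
                        max_mz_cells=2000, max_length=2000, max_width=2000),
        "grid": {"length": [359, 718, 1436], "width": [1, 2],
                 "v_pre": [2.8], "d_L4": [8.4, 14.0, 19.6],
                 "d_L4p1": [2.8, 5.6, 8.4], "d_L4p3": [2.8]},
    },
    "opt2": {
        "problem": dict(objective="first_n", fixed={"flat": 2.8}, max_mz_cells=359),
        "grid": {"length": [1, 2, 19, 179, 359], "width": [1, 2, 18, 179, 359]},
    },
    "opt3": {
        "problem": dict(objective="first_n", fixed={"flat": 2.8}, max_mz_cells=2000),
        "grid": {"length": [1, 2, 45, 500, 1000, 1523, 2000],
                 "width": [1, 2, 45, 500, 1000, 1523, 2000]},
    },
    "opt4": {
        "problem": dict(objective="first_n", fixed={"flat": 2.8}, exact_mz_cells=200),
        "grid": {"length": [1, 2, 4, 5, 8, 10, 20, 25, 40, 50, 100, 200],
                 "width": [1, 2, 4, 5, 8, 10, 20, 25, 40, 50, 100, 200]},
    },
    "opt5": {
        "problem": dict(objective="gametes", use_apoptosis=True,
                        free=("length", "width", "v_pre", "d_L4", "d_L4p1", "d_L4p3"),
                        max_mz_cells=2000, max_length=500, max_width=500),
        "grid": {"length": [112, 168, 224, 336], "width": [1],
                 "v_pre": [2.8], "d_L4": [5.6, 8.4, 11.2, 14.0],
                 "d_L4p1": [2.8, 5.6], "d_L4p3": [2.8]},
    },
    "opt6": {
        "problem": dict(objective="gametes", use_apoptosis=True,
                        free=("length", "width", "v_pre", "d_L4", "d_L4p1", "d_L4p3"),
                        max_mz_cells=2000, max_length=30, max_width=30),
        "grid": {"length": [18, 24, 30], "width": [8, 10, 12],
                 "v_pre": [2.8], "d_L4": [5.6, 9.8, 14.0],
                 "d_L4p1": [2.8, 3.8, 5.6], "d_L4p3": [2.8]},
    },
    "opt7": {
        "problem": dict(objective="gametes", use_apoptosis=True, fixed={"flat": 2.8},
                        max_mz_cells=2000),
        "grid": {"length": [1, 2, 4, 10, 100, 216, 359, 500],
                 "width": [1, 2, 4, 10, 100, 216, 359, 500]},
    },
    "opt8": {
        "problem": dict(objective="fitness", U=0.03, use_apoptosis=True,
                        production=True,
                        free=("v_pre", "d_L4", "d_L4p1", "d_L4p3"),
                        fixed={"length": 19, "width": 12}),
        "grid": {"v_pre": [2.8, 3.4], "d_L4": [2.8, 5.6, 8.4],
                 "d_L4p1": [2.8, 5.6, 8.4], "d_L4p3": [2.8, 5.6]},
    },
    "opt9": {
        "problem": dict(objective="fitness", U=0.48, use_apoptosis=True,
                        production=True,
                        free=("v_pre", "d_L4", "d_L4p1", "d_L4p3"),
                        fixed={"length": 19, "width": 12}),
        "grid": {"v_pre": [2.8, 3.4], "d_L4": [2.8, 5.6, 8.4],
                 "d_L4p1": [2.8, 5.6, 8.4], "d_L4p3": [2.8, 5.6]},
    },
    "opt10": {
        "problem": dict(objective="gametes", production=True,
                        free=("length", "width", "d_L4", "d_L4p1", "d_L4p3"),
                        fixed={"v_pre": 3.4},
                        max_mz_cells=500, max_length=30, max_width=30),
        "grid": {"length": [19, 25], "width": [12, 16],
                 "d_L4": [2.8, 4.2, 5.6], "d_L4p1": [2.8, 5.6, 8.4],
                 "d_L4p3": [5.6]},
    },
    "opt11": {
        "problem": dict(objective="gametes", production=True, premeiosis=True,
                        free=("d_L4", "d_L4p1", "d_L4p3"), fixed={"v_pre": 3.4},
                        geometry_override="experimental"),
        "grid": {"d_L4": [2.8, 4.2, 5.6], "d_L4p1": [2.8, 5.6, 8.4],
                 "d_L4p3": [2.8, 5.6]},
    },
    "opt12": {
        "problem": dict(objective="gametes", production=True, premeiosis=True,
                        variant="rate-scaled",
                        free=("d_L4", "d_L4p1", "d_L4p3"), fixed={"v_pre": 3.4},
                        geometry_override="experimental"),
        "grid": {"d_L4": [2.8, 4.2, 5.6], "d_L4p1": [2.8, 5.6, 8.4],
                 "d_L4p3": [2.8, 5.6]},
    },
    "opt13": {
        "problem": dict(objective="gametes", production=True, premeiosis=True,
                        variant="immortal-strand",
                        free=("d_L4", "d_L4p1", "d_L4p3"), fixed={"v_pre": 3.4},
                        geometry_override="experimental"),
        "grid": {"d_L4": [2.8, 4.2, 5.6], "d_L4p1": [2.8, 5.6, 8.4],
                 "d_L4p3": [2.8, 5.6]},
    },
}


def preset(name: str, budget: str = "desk") -> tuple[OptimizationProblem, dict]:
    """A Table-1-style optimization setup plus its search grid.

    ``budget="desk"`` uses 50 replicates per evaluation and the coarse grids
    above; ``budget="full"`` restores the 450-replicate protocol.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}")
    spec = PRESETS[name]
    kwargs = dict(spec["problem"])
    if kwargs.get("geometry_override") == "experimental":
        kwargs["geometry_override"] = load_fixtures().geometry
    kwargs["replicates"] = 50 if budget == "desk" else 450
    return OptimizationProblem(**kwargs), {k: list(v) for k, v in spec["grid"].items()}
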