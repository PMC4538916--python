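"""Grid search, threshold-acceptance MCMC, and apoptosis calibration."""

import numpy as np
import pytest

from gonadsim.lattice_simulator import SimulationConfig, run_mutation_accumulation
from gonadsim.optimization_engine import (
    EvalResult,
    OptimizationProblem,
    _overflow_pops,
    calibrate_apoptosis,
    evaluate_objective,
    grid_search,
    mcmc_posterior,
    preset,
)
from gonadsim.profiles import CellCycleProfile, MZGeometry
from gonadsim.schedules import ApoptosisProfile, ProductionSchedule, ProductionWindow


def quad_fn(prm, seed):
    return EvalResult((prm["x"] - 2.0) ** 2, 0.0, {}, True)


class TestGridSearch:
    def test_convex_function_refined_to_optimum(self):
        prob = OptimizationProblem(free=("x",), bounds={"x": (0.0, 4.0)})
        res = grid_search(prob, {"x": np.arange(0.0, 4.1, 1.0)},
                          refinement_levels=2, objective_fn=quad_fn)
        assert res.feasible
        assert abs(res.best_params["x"] - 2.0) <= 0.25  # final step size

    def test_refinement_never_worse_than_coarse(self):
        prob = OptimizationProblem(free=("x",), bounds={"x": (0.0, 4.0)})
        grid = {"x": np.arange(0.0, 4.1, 1.5)}
        coarse = grid_search(prob, grid, refinement_levels=0, objective_fn=quad_fn)
        fine = grid_search(prob, grid, refinement_levels=2, objective_fn=quad_fn)
        assert fine.best_value <= coarse.best_value + 1e-12

    def test_no_feasible_point_reported(self):
        prob = OptimizationProblem(free=("x",), bounds={"x": (0.0, 4.0)})
        fn = lambda prm, seed: EvalResult(1.0, 0.0, {"c": -1.0}, False)
        res = grid_search(prob, {"x": [0.0, 1.0]}, refinement_levels=0,
                          objective_fn=fn)
        assert not res.feasible

    def test_empty_grid_rejected(self):
        prob = OptimizationProblem(free=("x",))
        with pytest.raises(ValueError):
            grid_search(prob, {}, objective_fn=quad_fn)


class TestMcmcPosterior:
    def test_unacceptable_proposals_leave_posterior_at_start(self):
        prob = OptimizationProblem(free=("x",), bounds={"x": (0.0, 4.0)})
        fn = lambda prm, seed: EvalResult(10.0, 0.0, {}, True)  # all bad
        res = mcmc_posterior(prob, {"x": 2.0}, 0.0, {}, iterations=200, seed=1,
                             proposal_scales={"x": 0.3}, eps_objective=0.01,
                             objective_fn=fn)
        assert res.credible_intervals["x"] == (2.0, 2.0)

    def test_credible_interval_inside_epsilon_sublevel_set(self):
        prob = OptimizationProblem(free=("x",), bounds={"x": (0.0, 4.0)})
        res = mcmc_posterior(prob, {"x": 2.0}, 0.0, {}, iterations=2000, seed=2,
                             proposal_scales={"x": 0.1}, eps_objective=0.01,
                             objective_fn=quad_fn)
        lo, hi = res.credible_intervals["x"]
        # every retained sample does at least as well as the start, which on
        # the deterministic quadratic means (x - 2)^2 <= 0.01 a fortiori
        assert (lo - 2.0) ** 2 <= 0.01 + 1e-12
        assert (hi - 2.0) ** 2 <= 0.01 + 1e-12

    def test_posterior_respects_threshold_on_stochastic_objective(self):
        prob = OptimizationProblem(free=("x",), bounds={"x": (0.0, 4.0)})
        rng = np.random.default_rng(5)

        def noisy(prm, seed):
            return EvalResult((prm["x"] - 2.0) ** 2 + rng.normal(0, 0.003),
                              0.003, {}, True)

        start_val = 0.001
        res = mcmc_posterior(prob, {"x": 2.0}, start_val, {}, iterations=1500,
                             seed=3, proposal_scales={"x": 0.1},
                             eps_objective=0.01, objective_fn=noisy)
        assert res.posterior is not None and len(res.posterior) >= 1
        # all retained positions sit inside the epsilon sublevel set
        assert np.all((res.posterior[:, 0] - 2.0) ** 2 <= 0.01 + 0.01)

    def test_integer_parameters_stay_integral(self):
        prob = OptimizationProblem(free=("width",), max_width=50)
        fn = lambda prm, seed: EvalResult((prm["width"] - 7) ** 2, 0.0, {}, True)
        res = mcmc_posterior(prob, {"width": 7}, 0.0, {}, iterations=300, seed=4,
                             proposal_scales={"width": 2.0}, objective_fn=fn)
        assert np.allclose(res.posterior, np.rint(res.posterior))


class TestEvaluateObjective:
    def test_more_replicates_same_expectation_smaller_se(self):
        prob = OptimizationProblem(objective="first_n", first_n=300,
                                   fixed={"flat": 2.8}, max_mz_cells=100)
        few = evaluate_objective(prob, {"length": 5, "width": 10}, replicates=4,
                                 seed=1)
        many = evaluate_objective(prob, {"length": 5, "width": 10}, replicates=32,
                                  seed=2)
        assert abs(few.value - many.value) < 6 * (few.se + many.se)
        assert many.se < few.se

    def test_unbounded_flat_profile_respects_information_bound(self):
        # capacity >= n: the first 3000 exits cannot beat log2(3000) = 11.55
        prob = OptimizationProblem(objective="first_n", fixed={"flat": 2.8})
        ev = evaluate_objective(prob, {"length": 1, "width": 4000}, replicates=2,
                                seed=3)
        assert ev.value >= 11.55

    def test_slow_profile_breaks_production_constraint(self):
        prob = OptimizationProblem(objective="gametes", production=True,
                                   fixed={"flat": 28.0})
        ev = evaluate_objective(prob, {"length": 19, "width": 12}, replicates=3,
                                seed=4)
        assert not ev.feasible
        sperm_key = [k for k in ev.margins if k.startswith("sperm")][0]
        assert ev.margins[sperm_key] < 0

    def test_geometry_constraints_filter(self):
        prob = OptimizationProblem(fixed={"flat": 2.8}, max_mz_cells=100)
        ev = evaluate_objective(prob, {"length": 20, "width": 20}, replicates=1)
        assert not ev.feasible and ev.value == np.inf

    def test_relaxing_cell_cap_never_worsens_optimum(self):
        grids = {"length": [1, 2], "width": [64, 128, 256]}
        vals = {}
        for cap in (128, 256):
            prob = OptimizationProblem(objective="first_n", first_n=500,
                                       fixed={"flat": 2.8}, max_mz_cells=cap,
                                       replicates=8)
            res = grid_search(prob, grids, refinement_levels=0, seed=6)
            vals[cap] = res.best_value
        assert vals[256] <= vals[128] + 1e-9


class TestCalibrateApoptosis:
    @staticmethod
    def _observed_schedule(geometry, profile, queue, truth, seeds, rng):
        """Oocyte counts per stage window when leavers (pure size-overflow
        efflux) survive with the truth profile's probabilities."""
        ends = [54.0, 78.0, 102.0, 126.0, 150.0]
        counts = np.zeros(len(ends))
        for s in seeds:
            res = run_mutation_accumulation(SimulationConfig(seed=s), geometry,
                                            profile, n_exits=16000)
            et = res.exits["exit_time_h"].to_numpy()
            ec = res.exits["exit_clock"].to_numpy()
            popped = _overflow_pops(et, ec, queue)
            surv = rng.random(16000) >= truth.probabilities_for(16000)
            prev = 0
            for j, te in enumerate(ends):
                i = int(np.searchsorted(et, te, side="right"))
                ptot = int(popped[i - 1]) if i > 0 else 0
                counts[j] += surv[np.arange(44 + prev, 44 + ptot)].sum()
                prev = ptot
        counts /= len(seeds)
        windows = [ProductionWindow(0.0, 31.3, "sperm", 44)] + [
            ProductionWindow(30.0 + 24 * j, 54.0 + 24 * j, "oocyte",
                             int(round(cj)))
            for j, cj in enumerate(counts)
        ]
        return ProductionSchedule(windows=tuple(windows))

    def test_zero_apoptosis_recovered(self, fixtures):
        geometry = MZGeometry.rectangular(19, 12)
        profile = CellCycleProfile.flat(2.8)
        rng = np.random.default_rng(3)
        sched = self._observed_schedule(geometry, profile,
                                        fixtures.meiotic_queue,
                                        ApoptosisProfile.zero(),
                                        seeds=range(3), rng=rng)
        ap = calibrate_apoptosis(sched, geometry, profile,
                                 fixtures.meiotic_queue, seed=5, replicates=3)
        assert max(ap.probabilities) < 0.03

    def test_roundtrip_recovers_band_probabilities(self, fixtures):
        geometry = MZGeometry.rectangular(19, 12)
        profile = CellCycleProfile.flat(2.8)
        queue = fixtures.meiotic_queue
        # synthetic truth: the study's stage-wise probabilities on index
        # bands aligned with this profile's window efflux
        ref = run_mutation_accumulation(SimulationConfig(seed=42), geometry,
                                        profile, n_exits=16000)
        et = ref.exits["exit_time_h"].to_numpy()
        ec = ref.exits["exit_clock"].to_numpy()
        popped = _overflow_pops(et, ec, queue)
        bnd = [int(popped[int(np.searchsorted(et, te, "right")) - 1]) + 44
               for te in (54.0, 78.0, 102.0, 126.0)]
        truth = ApoptosisProfile(tuple(bnd), (0.68, 0.83, 0.86, 0.98, 0.99))
        rng = np.random.default_rng(7)
        sched = self._observed_schedule(geometry, profile, queue, truth,
                                        seeds=range(100, 105), rng=rng)
        ap = calibrate_apoptosis(sched, geometry, profile, queue, seed=11,
                                 replicates=5)
        err = np.abs(np.array(ap.probabilities) - np.array(truth.probabilities))
        assert err.max() < 0.05

    def test_unattainable_schedule_reported(self, fixtures):
        # a tiny slow organ produces no MeZ overflow inside the windows
        sched = ProductionSchedule(windows=(
            ProductionWindow(0.0, 31.3, "sperm", 44),
            ProductionWindow(30.0, 54.0, "oocyte", 23),
        ))
        with pytest.raises(ValueError, match="unattainable"):
            calibrate_apoptosis(sched, MZGeometry.rectangular(2, 2),
                                CellCycleProfile.flat(20.0),
                                fixtures.meiotic_queue, seed=1, replicates=1)


class TestPresets:
    def test_all_presets_materialize(self):
        for name in [f"opt{i}" for i in range(1, 14)]:
            problem, grid = preset(name, budget="desk")
            assert problem.replicates == 50
            assert grid
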