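"""DNA normalization, phase-length inversion, DEMD/FLM metrics, profile fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect

from _oracles import cemd_flow_oracle
from gonadsim.cellcycle_fitting import (
    DEMDHistogramSet,
    FitSpec,
    FLMMatrix,
    PulseChaseDataset,
    bootstrap_ci,
    build_demd_histograms,
    cemd,
    demd_distance,
    fit_profile,
    flm_distance,
    flm_matrix,
    normalize_dna,
    phase_duration_profile,
    phase_lengths_from_indices,
)
from gonadsim.synthetic_data import (
    DEFAULT_PHASE_FRACTIONS,
    SyntheticSpec,
    default_truth_profile,
    fitting_geometry,
    generate_pulse_chase,
)


class TestNormalizeDna:
    def test_already_normalized_is_identity(self, rng):
        v = np.concatenate([np.full(60, 2.0), np.full(40, 4.0)])
        # quantiles: q10 = 2, q85 = 4 -> unchanged
        out = normalize_dna(v)
        assert np.allclose(out, v)

    def test_scale_invariance(self, rng):
        v = rng.uniform(100, 900, size=500)
        assert np.allclose(normalize_dna(v), normalize_dna(3.7 * v))
        assert np.allclose(normalize_dna(v), normalize_dna(v + 55.0))

    def test_uniform_sample_affine_map(self):
        v = np.linspace(0.0, 1.0, 100_001)
        out = normalize_dna(v)
        # 0.1 -> 2C, 0.85 -> 4C, 0.475 (midpoint of the quantile span) -> 3C
        assert out[np.argmin(np.abs(v - 0.1))] == pytest.approx(2.0, abs=1e-3)
        assert out[np.argmin(np.abs(v - 0.85))] == pytest.approx(4.0, abs=1e-3)
        assert out[np.argmin(np.abs(v - 0.475))] == pytest.approx(3.0, abs=1e-3)

    def test_degenerate_and_short_inputs_rejected(self):
        with pytest.raises(ValueError):
            normalize_dna(np.ones(100))
        with pytest.raises(ValueError):
            normalize_dna(np.arange(5))


class TestPhaseLengths:
    def test_zero_g1_index(self):
        lengths = phase_lengths_from_indices(0.0, 0.5, 0.45, 0.05)
        assert lengths[0] == 0.0

    def test_full_cycle_boundary(self):
        lengths = phase_lengths_from_indices(0.25, 0.25, 0.25, 0.25)
        assert sum(lengths) == pytest.approx(1.0)

    def test_half_index_matches_bisection_oracle(self):
        # solve F(x) = 0.5 with F(x) = 2 - 2^(1-x) independently
        x_oracle = bisect(lambda x: 2 - 2 ** (1 - x) - 0.5, 0, 1, xtol=1e-12)
        lengths = phase_lengths_from_indices(0.5, 0.5, 0.0, 0.0)
        assert lengths[0] == pytest.approx(x_oracle, abs=1e-9)
        assert lengths[0] == pytest.approx(1 - np.log2(1.5), abs=1e-12)

    def test_inversion_roundtrip(self):
        # lengths -> indices through F -> invert -> same lengths
        lengths = np.array(DEFAULT_PHASE_FRACTIONS)
        bounds = np.concatenate([[0.0], np.cumsum(lengths)])
        F = lambda x: 2 - 2 ** (1 - x)
        indices = np.diff(F(bounds))
        back = phase_lengths_from_indices(*indices)
        assert np.allclose(back, lengths, atol=1e-12)

    def test_simulated_population_inverts_within_one_percent(self):
        # simulate an asynchronous exponential-age population, recompute the
        # observed phase indices, re-invert: lengths within 1 %
        from gonadsim.lattice_simulator import SimulationConfig, run_pulse_chase
        from gonadsim.profiles import CellCycleProfile, MZGeometry

        fr = DEFAULT_PHASE_FRACTIONS
        prof = CellCycleProfile((1, 4), (0.0,), ((4.0, 4.0),),
                                phase_fractions=((1, 4, fr),))
        frames = [
            run_pulse_chase(
                SimulationConfig(seed=s, pre_run_h=0.0, chase_times_h=(0.0,)),
                MZGeometry.rectangular(4, 40), prof)
            for s in range(40)
        ]
        rec = pd.concat(frames)
        idx = rec["phase"].value_counts(normalize=True)
        back = phase_lengths_from_indices(idx.get("G1", 0.0), idx["S"],
                                          idx["G2"], idx["M"])
        assert np.allclose(back, fr, atol=0.01)

    def test_invalid_indices_rejected(self):
        with pytest.raises(ValueError):
            phase_lengths_from_indices(1.2, -0.2, 0.0, 0.0)
        with pytest.raises(ValueError):
            phase_lengths_from_indices(0.5, 0.1, 0.1, 0.1)


def _dataset(records):
    return PulseChaseDataset(records, {"DMMZ": (1, 6), "MMZ": (7, 11)})


def _records(rows, dna, edu, m=None, chase=0.0, arm=0):
    n = len(rows)
    return pd.DataFrame(
        {
            "arm_id": arm,
            "chase_h": chase,
            "row": rows,
            "dna_c": dna,
            "edu": edu,
            "m_flag": m if m is not None else [0] * n,
        }
    )


class TestDemdHistograms:
    def test_empty_dataset_all_zero(self):
        ds = _dataset(_records([], [], []))
        hs = build_demd_histograms(ds, n_bins=16)
        assert hs.hist.sum() == 0

    def test_single_record_mass_one(self):
        ds = _dataset(_records([3], [2.5], [1]))
        hs = build_demd_histograms(ds, n_bins=16)
        assert hs.hist.sum() == 1
        assert hs.counts.sum() == 1

    def test_edu_split_counts(self, rng):
        n = 100
        edu = np.zeros(n, dtype=int)
        edu[:60] = 1
        ds = _dataset(_records([3] * n, rng.uniform(2, 4, n), edu))
        hs = build_demd_histograms(ds)
        by_edu = {k[2]: c for k, c in zip(hs.keys, hs.counts) if k[1] == "DMMZ"}
        assert by_edu[1] == 60 and by_edu[0] == 40

    def test_out_of_map_records_warn(self):
        ds = _dataset(_records([3, 99], [2.5, 2.5], [0, 0]))
        with pytest.warns(UserWarning, match="outside the compartment map"):
            hs = build_demd_histograms(ds)
        assert hs.counts.sum() == 1


class TestCemd:
    def test_identical_histograms_zero(self):
        assert cemd([1, 2, 3, 4], [1, 2, 3, 4]) == 0.0

    def test_adjacent_unit_masses(self):
        # one unit of mass moved 1 bin on a 4-bin circle (wrap distance 1)
        assert cemd([1, 0, 0, 0], [0, 0, 0, 1]) == pytest.approx(1.0)

    def test_opposite_bins_half_circle(self):
        assert cemd([1, 0, 0, 0], [0, 0, 1, 0]) == pytest.approx(2.0)

    def test_matches_flow_oracle_on_random_pairs(self, rng):
        for _ in range(25):
            p = rng.integers(0, 10, size=8) + (1 if rng.random() < 0.5 else 0)
            q = rng.integers(0, 10, size=8)
            if p.sum() == 0 or q.sum() == 0:
                continue
            assert cemd(p, q) == pytest.approx(cemd_flow_oracle(p, q), abs=1e-8)

    @given(
        p=st.lists(st.integers(0, 20), min_size=6, max_size=6),
        q=st.lists(st.integers(0, 20), min_size=6, max_size=6),
        r=st.lists(st.integers(0, 20), min_size=6, max_size=6),
    )
    @settings(max_examples=200, deadline=None)
    def test_metric_properties(self, p, q, r):
        if min(sum(p), sum(q), sum(r)) == 0:
            return
        dpq = cemd(p, q)
        assert dpq >= 0
        assert dpq == pytest.approx(cemd(q, p))
        pn = np.asarray(p, float) / sum(p)
        qn = np.asarray(q, float) / sum(q)
        if np.allclose(pn, qn):
            assert dpq == pytest.approx(0.0, abs=1e-12)
        assert dpq <= cemd(p, r) + cemd(r, q) + 1e-9

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValueError):
            cemd([1, 0], [1, 0, 0])
        with pytest.raises(ValueError):
            cemd([0, 0], [1, 0])


class TestDemdDistance:
    def _set(self, hists, counts):
        keys = tuple((0.0, "DMMZ", i) for i in range(len(hists)))
        return DEMDHistogramSet(keys, np.asarray(hists, float),
                                np.asarray(counts, float))

    def test_identical_sets_zero(self):
        g = self._set([[1, 2], [3, 4]], [3, 7])
        assert demd_distance(g, g) == 0.0

    def test_printed_formula_example(self):
        # one stratum, 5 and 5 cells, unit CEMD -> 5 * 5 * 1 = 25
        g = self._set([[5, 0, 0, 0]], [5])
        h = self._set([[0, 5, 0, 0]], [5])
        assert demd_distance(g, h) == pytest.approx(25.0)

    def test_symmetry(self, rng):
        g = self._set(rng.integers(0, 9, (3, 8)), [4, 5, 6])
        h = self._set(rng.integers(0, 9, (3, 8)), [7, 8, 9])
        assert demd_distance(g, h) == pytest.approx(demd_distance(h, g))

    def test_mismatched_partitions_rejected(self):
        g = self._set([[1, 0]], [1])
        h = DEMDHistogramSet(((1.0, "MMZ", 0),), np.array([[1.0, 0.0]]),
                             np.array([1.0]))
        with pytest.raises(ValueError):
            demd_distance(g, h)


class TestFlm:
    def test_all_labeled_mitoses(self):
        ds = _dataset(_records([3] * 5, [4.0] * 5, [1] * 5, m=[1] * 5))
        fm = flm_matrix(ds)
        defined = fm.entries[fm.counts > 0]
        assert np.allclose(defined, 1.0)

    def test_counting(self):
        edu = [1] * 3 + [0] * 7
        ds = _dataset(_records([3] * 10, [4.0] * 10, edu, m=[1] * 10))
        fm = flm_matrix(ds)
        assert fm.entries[fm.counts > 0][0] == pytest.approx(0.3)

    def test_undefined_strata_have_zero_count(self):
        ds = _dataset(_records([3], [2.0], [0], m=[0]))
        fm = flm_matrix(ds)
        assert (fm.counts == 0).any()
        assert np.isnan(fm.entries[fm.counts == 0]).all()

    def test_distance_formula_example(self):
        keys = ((0.0, "DMMZ"),)
        g = FLMMatrix(keys, np.array([0.8]), np.array([10.0]))
        h = FLMMatrix(keys, np.array([0.3]), np.array([20.0]))
        assert flm_distance(g, h) == pytest.approx(10 * 20 * 0.25)

    def test_distance_scales_with_count_product(self):
        keys = ((0.0, "DMMZ"),)
        g = FLMMatrix(keys, np.array([0.8]), np.array([10.0]))
        h = FLMMatrix(keys, np.array([0.3]), np.array([20.0]))
        g3 = FLMMatrix(keys, np.array([0.8]), np.array([30.0]))
        h3 = FLMMatrix(keys, np.array([0.3]), np.array([60.0]))
        assert flm_distance(g3, h3) == pytest.approx(9 * flm_distance(g, h))

    def test_identical_zero(self):
        keys = ((0.0, "DMMZ"),)
        g = FLMMatrix(keys, np.array([0.8]), np.array([10.0]))
        assert flm_distance(g, g) == 0.0


@pytest.fixture(scope="module")
def small_fit_spec():
    return FitSpec(
        geometry=fitting_geometry(),
        phase_fractions=DEFAULT_PHASE_FRACTIONS,
        distal_grid=(3.8, 4.2, 4.6),
        proximal_grid=(2.8, 3.2),
        sim_arms=30,
    )


class TestFitProfile:
    def test_noise_free_data_recovered_exactly(self, small_fit_spec):
        spec = SyntheticSpec.default(seed=31, arms_per_chase=12, noise_cv=0.0,
                                     edu_misclassification=0.0, arm_speed_cv=0.0)
        ds, truth = generate_pulse_chase(spec)
        res = fit_profile(ds, small_fit_spec, seed=1)
        assert res.point == (4.2, 2.8)
        assert res.ratio == pytest.approx(truth["ratio"])

    def test_consistency_error_shrinks_with_sample_size(self, small_fit_spec):
        errs = []
        for arms in (2, 8, 24):
            err_runs = []
            for k in range(3):
                ds, _ = generate_pulse_chase(
                    SyntheticSpec.default(seed=200 + 10 * arms + k,
                                          arms_per_chase=arms, noise_cv=0.0,
                                          edu_misclassification=0.0,
                                          arm_speed_cv=0.0))
                res = fit_profile(ds, small_fit_spec, seed=1)
                err_runs.append(abs(res.ratio - 1.5))
            errs.append(np.mean(err_runs))
        assert errs[-1] <= errs[0]
        assert errs[-1] == pytest.approx(0.0, abs=1e-9)

    def test_identical_arms_give_zero_width_interval(self, small_fit_spec):
        spec = SyntheticSpec.default(seed=77, arms_per_chase=6, noise_cv=0.0,
                                     edu_misclassification=0.0, arm_speed_cv=0.0)
        ds, _ = generate_pulse_chase(spec)
        # make every arm within a chase stratum literally identical
        rec = ds.records
        parts = []
        for t in sorted(rec.chase_h.unique()):
            one = rec[(rec.chase_h == t)]
            first_arm = one[one.arm_id == one.arm_id.min()]
            for j in range(4):
                dup = first_arm.copy()
                dup["arm_id"] = 1000 * int(t * 10 + 1) + j
                parts.append(dup)
        ds2 = PulseChaseDataset(pd.concat(parts, ignore_index=True),
                                ds.compartments)
        out = bootstrap_ci(ds2, small_fit_spec, n_boot=50, seed=3, sim_seed=1)
        lo, hi = out["ci"]
        assert lo == hi

    def test_bootstrap_preserves_arm_counts_per_stratum(self, small_fit_spec):
        spec = SyntheticSpec.default(seed=78, arms_per_chase=3,
                                     chase_times_h=(0.0, 2.0))
        ds, _ = generate_pulse_chase(spec)
        seen = []

        def count_arms(d):
            seen.append(d.records.groupby("chase_h")["arm_id"].nunique().to_dict())
            return 1.0

        bootstrap_ci(ds, small_fit_spec, n_boot=3, seed=5, fit_fn=count_arms)
        for counts in seen:
            # resampling with replacement, re-labelled uniquely per draw
            assert counts == {0.0: 3, 2.0: 3}


class TestPhaseDurationProfile:
    def test_flat_profile_flat_durations(self):
        prof = default_truth_profile(ratio=1.0)
        out = phase_duration_profile(prof, 11)
        assert out["G2"].nunique() == 1

    def test_durations_proportional_to_total(self):
        prof = default_truth_profile(ratio=2.0)
        out = phase_duration_profile(prof, 11)
        assert out.loc[0, "G2"] == pytest.approx(2 * out.loc[10, "G2"])
        assert np.allclose(out[["G1", "S", "G2", "M"]].sum(axis=1), out["total"])

    def test_distal_g2_extension_recovered_with_correct_sign(self, small_fit_spec):
        # truth has longer distal cycles; with fixed fractions the fitted G2
        # must decrease from row 1 to the proximal end
        ds, _ = generate_pulse_chase(
            SyntheticSpec.default(seed=55, arms_per_chase=12, noise_cv=0.0,
                                  edu_misclassification=0.0, arm_speed_cv=0.0))
        res = fit_profile(ds, small_fit_spec, seed=1)
        out = phase_duration_profile(res.profile, 11)
        assert out.loc[0, "G2"] > out.loc[10, "G2"]
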