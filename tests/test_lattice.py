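"""Lattice movement rules, event loop invariants, and pulse-chase output."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gonadsim.lattice_simulator import (
    Lattice,
    SimulationConfig,
    apply_premeiotic_arrest,
    place_daughter,
    rescale_pending_division,
    run_mutation_accumulation,
    run_pulse_chase,
    sample_division_time,
)
from gonadsim.profiles import CellCycleProfile, MZGeometry


class TestSampleDivisionTime:
    def test_one_percent_uniform_bounds(self, rng):
        draws = [sample_division_time(2.8, rng) for _ in range(2000)]
        assert min(draws) >= 2.8 * 0.995 - 1e-12
        assert max(draws) <= 2.8 * 1.005 + 1e-12

    def test_zero_jitter_is_exact(self, rng):
        assert sample_division_time(5.0, rng, jitter=0.0) == 5.0

    def test_mean_matches_requested_length(self, rng):
        draws = 4.0 * (1.0 + 0.01 * (rng.random(100_000) - 0.5))
        assert abs(draws.mean() - 4.0) < 1e-3

    def test_nonpositive_mean_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_division_time(0.0, rng)


class TestRescalePendingDivision:
    def test_equal_lengths_unchanged(self):
        p = CellCycleProfile((1, 5), (0.0,), ((2.8, 2.8),))
        assert rescale_pending_division(2.0, 1, 4, p) == pytest.approx(2.0)

    def test_faster_row_halves_remaining(self):
        p = CellCycleProfile((1, 2), (0.0,), ((4.0, 2.0),), min_cycle_length=1.0)
        assert rescale_pending_division(2.0, 1, 2, p) == pytest.approx(1.0)

    def test_slower_row_doubles_remaining(self):
        p = CellCycleProfile((1, 2), (0.0,), ((2.8, 5.6),))
        assert rescale_pending_division(1.0, 1, 2, p) == pytest.approx(2.0)


class TestPlacementRules:
    def test_empty_slot_in_row_keeps_both_daughters(self):
        lat = Lattice([3])
        lat.occupy(0, 0, 0)
        out = place_daughter(lat, 0, 0, cell_id=1)
        assert out["exited"] is None
        assert lat.occ[0] == 2  # both cells in row 1
        lat.check_occupancy()

    def test_full_two_row_column_exports_exactly_one_cell(self):
        lat = Lattice([1, 1], max_cells=8)
        lat.occupy(0, 0, 0)
        lat.occupy(1, 0, 1)
        out = place_daughter(lat, 0, 0, cell_id=2)
        assert out["exited"] == 1  # the proximal occupant is pushed out
        assert lat.n_cells == 2
        lat.check_occupancy()

    def test_full_row_with_empty_next_row_uses_rule_two(self):
        lat = Lattice([2, 2], max_cells=8)
        lat.occupy(0, 0, 0)
        lat.occupy(0, 1, 1)
        out = place_daughter(lat, 0, 0, cell_id=2)
        assert out["exited"] is None
        assert lat.occ[0] == 2 and lat.occ[1] == 1
        # row 1 unchanged
        assert set(lat.grid[0, :2]) == {0, 1}
        lat.check_occupancy()

    def test_displaced_cells_report_row_changes(self):
        lat = Lattice([1, 1, 1], max_cells=8)
        for r in range(3):
            lat.occupy(r, 0, r)
        out = place_daughter(lat, 0, 0, cell_id=3)
        # the whole column shifts: cells 1 and 2 move/exit
        assert out["exited"] == 2
        moved_ids = {m[0] for m in out["moved"]}
        assert 1 in moved_ids
        lat.check_occupancy()


class TestEventLoopInvariants:
    @given(
        length=st.integers(1, 4),
        width=st.integers(1, 5),
        n_exits=st.integers(1, 40),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=40, deadline=None)
    def test_conservation_and_occupancy(self, length, width, n_exits, seed):
        geo = MZGeometry.rectangular(length, width)
        res = run_mutation_accumulation(
            SimulationConfig(seed=seed), geo, CellCycleProfile.flat(2.8),
            n_exits=n_exits,
        )
        # divisions + 1 = cells in MZ + cells exited
        assert res.divisions + 1 == len(res.mz_depths) + res.n_exits
        assert len(res.mz_depths) <= length * width

    def test_exits_ordered_fifo(self, flat_profile):
        res = run_mutation_accumulation(
            SimulationConfig(seed=5), MZGeometry.rectangular(3, 5), flat_profile,
            n_exits=200,
        )
        assert list(res.exits["exit_index"]) == list(range(1, 201))
        assert np.all(np.diff(res.exits["exit_time_h"]) >= 0)

    def test_identical_seed_identical_exits(self, flat_profile):
        geo = MZGeometry.rectangular(4, 6)
        a = run_mutation_accumulation(SimulationConfig(seed=77), geo, flat_profile,
                                      n_exits=300)
        b = run_mutation_accumulation(SimulationConfig(seed=77), geo, flat_profile,
                                      n_exits=300)
        assert a.exits.equals(b.exits)
        assert np.array_equal(a.div_times_h, b.div_times_h)

    def test_balanced_tree_limit(self, flat_profile):
        """With capacity >= n and a flat profile, growing 2^k cells gives a
        balanced tree: mean pedigree depth k (tolerance 0.1, 200 runs)."""
        k = 10
        geo = MZGeometry.rectangular(1, 2**k)
        means = []
        for s in range(200):
            res = run_mutation_accumulation(
                SimulationConfig(seed=s), geo, flat_profile,
                n_exits=None, n_pop=2**k,
            )
            assert res.n_exits == 0
            means.append(res.mz_depths.mean())
        assert abs(np.mean(means) - k) < 0.1

    def test_throughput_halves_when_cycle_doubles(self):
        geo = MZGeometry.rectangular(4, 8)
        counts = {}
        for tau in (2.8, 5.6):
            prof = CellCycleProfile.flat(tau)
            res = run_mutation_accumulation(SimulationConfig(seed=3), geo, prof,
                                            n_exits=4000)
            et = res.exits["exit_time_h"].to_numpy()
            # fixed wall-clock window, well past both fill phases
            counts[tau] = ((et > 60.0) & (et <= 200.0)).sum()
        ratio = counts[2.8] / counts[5.6]
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_geometry_shrinkage_conserves_cells(self):
        geo = MZGeometry((0.0, 200.0), ((6, 6, 6), (3, 3, 3)))
        res = run_mutation_accumulation(
            SimulationConfig(seed=9), geo, CellCycleProfile.flat(2.8), n_exits=400,
        )
        assert res.divisions + 1 == len(res.mz_depths) + res.n_exits
        assert len(res.mz_depths) <= 9  # final shrunken capacity


class TestPremeioticArrest:
    def test_rule_is_strict_inequality(self):
        assert apply_premeiotic_arrest(0.05, 0.05) == "cycling"
        assert apply_premeiotic_arrest(0.06, 0.05) == "arrested"

    def test_zero_experimental_index_arrests_every_g2_entrant(self):
        prof = CellCycleProfile(
            (1, 6), (0.0,), ((3.0, 3.0),), min_cycle_length=2.8,
            phase_fractions=((1, 6, (0.07, 0.50, 0.40, 0.03)),),
        )
        mi = (np.inf, np.inf, np.inf, 0.0, 0.0, 0.0)  # PMZ = rows 4-6
        cfg = SimulationConfig(seed=21, premeiosis=True, mitotic_index_profile=mi,
                               chase_times_h=(2.0, 8.0))
        rec = run_pulse_chase(cfg, MZGeometry.rectangular(6, 20), prof)
        for t in (2.0, 8.0):
            snap = rec[rec.chase_h == t]
            pmz = snap[snap.row >= 4]
            # the arrest rule pins the PMZ mitotic index at the ceiling: with
            # a zero ceiling, a G2 entrant arrests whenever any row-mate is
            # in M, so only straggler M cells survive at any instant
            assert (pmz.phase == "M").mean() <= 0.1
            assert (pmz.phase == "arrested").sum() > 0
            # arrested cells keep G2 DNA content
            assert (pmz.loc[pmz.phase == "arrested", "dna_c"] == 4.0).all()


class TestPulseChase:
    def test_chase_zero_labels_exactly_s_phase(self):
        prof = CellCycleProfile(
            (1, 5), (0.0,), ((3.2, 3.2),),
            phase_fractions=((1, 5, (0.07, 0.50, 0.40, 0.03)),),
        )
        rec = run_pulse_chase(SimulationConfig(seed=4, chase_times_h=(0.0,)),
                              MZGeometry.rectangular(5, 8), prof)
        labeled = rec[rec.edu == 1]
        assert len(labeled) > 0
        assert (labeled.phase == "S").all()
        assert ((labeled.dna_c > 2.0) & (labeled.dna_c < 4.0)).all()

    def test_chase_zero_unlabeled_histogram_bimodal(self):
        prof = CellCycleProfile(
            (1, 5), (0.0,), ((3.2, 3.2),),
            phase_fractions=((1, 5, (0.07, 0.50, 0.40, 0.03)),),
        )
        rec = run_pulse_chase(SimulationConfig(seed=4, chase_times_h=(0.0,)),
                              MZGeometry.rectangular(5, 8), prof)
        unlabeled = rec[rec.edu == 0]
        assert (np.isin(unlabeled.dna_c, (2.0, 4.0))).all()
        assert (unlabeled.dna_c == 2.0).any() and (unlabeled.dna_c == 4.0).any()

    def test_flm_rise_lag_matches_single_cell_oracle(self):
        """EdU-labeled mitoses appear only after the G2 lag: a cell at the
        end of S needs the whole G2 span before reaching M, so the first
        labeled M cells appear at a chase just shorter than G2, and by a
        chase well past G2 (but shorter than G2+S) labeled mitoses exist."""
        fr = (0.07, 0.50, 0.40, 0.03)
        tau = 5.0
        g2_h = fr[2] * tau
        prof = CellCycleProfile(
            (1, 5), (0.0,), ((tau, tau),),
            phase_fractions=((1, 5, fr),),
        )
        chases = (0.0, 0.5 * g2_h, g2_h + 1.0)
        rec = run_pulse_chase(SimulationConfig(seed=8, chase_times_h=chases),
                              MZGeometry.rectangular(5, 60), prof)
        flm = {
            t: ((rec.chase_h == t) & (rec.m_flag == 1) & (rec.edu == 1)).sum()
            for t in chases
        }
        assert flm[0.0] == 0
        assert flm[chases[1]] == 0  # still inside the G2 lag
        assert flm[chases[2]] > 0

    def test_missing_phase_fractions_rejected(self, flat_profile):
        with pytest.raises(ValueError):
            run_pulse_chase(SimulationConfig(seed=1),
                            MZGeometry.rectangular(3, 3), flat_profile)
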