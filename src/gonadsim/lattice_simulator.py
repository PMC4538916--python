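"""Agent-based simulation of germ-cell proliferation on a cylindrical lattice.

Two run modes share one event-driven core (see ``_kernels``):

* :func:`run_mutation_accumulation` seeds a single progenitor at the distal
  end and tracks the pedigree depth (divisions from the progenitor) of every
  cell that leaves the mitotic zone, assigning gamete/apoptosis fates through
  the meiotic-zone FIFO.

* :func:`run_pulse_chase` starts from a pre-filled asynchronous population,
  marks S-phase cells with EdU at time zero, and snapshots per-cell DNA
  content, phase, and EdU status at the requested chase times, emulating an
  EdU pulse-chase experiment on one gonadal arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import INF
from .profiles import CellCycleProfile, MZGeometry, interpolate_cycle_length
from .schedules import (
    ApoptosisProfile,
    GameteAccounting,
    MeioticQueue,
    ProductionSchedule,
    assign_gamete_fates,
)

__all__ = [
    "CellState",
    "SimulationConfig",
    "SimulationResult",
    "Lattice",
    "sample_division_time",
    "place_daughter",
    "rescale_pending_division",
    "apply_premeiotic_arrest",
    "run_mutation_accumulation",
    "run_pulse_chase",
]

VARIANTS = {"standard": 0, "immortal-strand": 1, "rate-scaled": 2}
PHASE_NAMES = np.array(["G1", "S", "G2", "M", "arrested"])


@dataclass
class CellState:
    """A single cell on the lattice (used by the thin operation wrappers;
    the bulk simulations keep cell state in flat arrays)."""

    cell_id: int
    row: int
    slot: int
    pedigree_depth: float = 0.0
    phase: str = "G1"
    edu_labeled: bool = False
    next_event_time: float = 0.0
    birth_order: int = 0

    def __post_init__(self) -> None:
        if self.pedigree_depth < 0:
            raise ValueError("pedigree depth must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Run-level knobs shared by both simulation modes."""

    seed: int = 0
    division_jitter: float = 0.01  # uniform width as a fraction of cycle length
    pedigree_variant: str = "standard"
    premeiosis: bool = False
    mitotic_index_profile: tuple[float, ...] | None = None  # per row, 1-based
    pre_run_h: float = 2.0
    chase_times_h: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 5.0, 6.0, 8.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.division_jitter < 1.0:
            raise ValueError("division jitter must lie in [0, 1)")
        if self.pedigree_variant not in VARIANTS:
            raise ValueError(f"unknown pedigree variant {self.pedigree_variant!r}")
        if any(t < 0 for t in self.chase_times_h):
            raise ValueError("chase times must be nonnegative")
        if self.premeiosis and self.mitotic_index_profile is None:
            raise ValueError("premeiosis requires an experimental mitotic-index profile")


@dataclass
class SimulationResult:
    """Ordered MZ exits plus run bookkeeping from a mutation-accumulation run."""

    exits: pd.DataFrame
    divisions: int
    div_times_h: np.ndarray
    mz_depths: np.ndarray
    sperm_times_h: np.ndarray
    oocyte_times_h: np.ndarray

    @property
    def n_exits(self) -> int:
        return len(self.exits)

    def clock_at(self, t_h: float) -> int:
        """Cumulative divisions completed by wall-clock time ``t_h``."""
        return int(np.searchsorted(self.div_times_h, t_h, side="right"))


def sample_division_time(mean_length: float, rng, jitter: float = 0.01) -> float:
    """Time to next division: uniform with the given mean, width
    ``jitter``x the mean (1 % by default), drawn independently per daughter."""
    if mean_length <= 0:
        raise ValueError("mean cycle length must be positive")
    if not 0.0 <= jitter < 1.0:
        raise ValueError("jitter fraction must lie in [0, 1)")
    u = rng.random() if hasattr(rng, "random") else float(rng)
    return mean_length * (1.0 + jitter * (u - 0.5))


def rescale_pending_division(
    cell: "CellState | float",
    old_row: int,
    new_row: int,
    profile: CellCycleProfile,
    *,
    clock: float = 0.0,
    now: float = 0.0,
) -> float:
    """Remaining waiting time scaled by the cycle-length ratio new/old row.

    Accepts either a :class:`CellState` (updated in place, absolute time) or
    a bare remaining-time float (returned scaled).
    """
    ratio = interpolate_cycle_length(profile, new_row, clock) / interpolate_cycle_length(
        profile, old_row, clock
    )
    if isinstance(cell, CellState):
        cell.next_event_time = now + (cell.next_event_time - now) * ratio
        return cell.next_event_time
    return float(cell) * ratio


def apply_premeiotic_arrest(
    simulated_mitotic_index: float,
    experimental_index: float,
) -> str:
    """Fate decision for a cell entering G2 in the proximal MZ: the cell
    arrests (leaves the mitotic cycle, retaining G2 DNA content) exactly when
    the simulated local mitotic index exceeds the experimentally derived
    index at its row."""
    return "arrested" if simulated_mitotic_index > experimental_index else "cycling"


class Lattice:
    """Small explicit lattice used by the placement-rule wrapper and tests."""

    def __init__(self, capacities: Sequence[int], max_cells: int | None = None):
        caps = np.asarray(capacities, dtype=np.int64)
        if caps.size == 0 or np.any(caps < 1):
            raise ValueError("capacities must be >= 1 and nonempty")
        self.caps = caps
        self.n_rows = caps.size
        wmax = int(caps.max())
        self.grid = np.full((self.n_rows, wmax), -1, dtype=np.int64)
        self.occ = np.zeros(self.n_rows, dtype=np.int64)
        n = int(caps.sum()) + 8 if max_cells is None else max_cells
        self.row_of = np.full(n, -1, dtype=np.int64)
        self.slot_of = np.full(n, -1, dtype=np.int64)

    def occupy(self, row: int, slot: int, cell_id: int) -> None:
        if self.grid[row, slot] >= 0:
            raise ValueError("slot already occupied")
        self.grid[row, slot] = cell_id
        self.occ[row] += 1
        self.row_of[cell_id] = row
        self.slot_of[cell_id] = slot

    @property
    def n_cells(self) -> int:
        return int(self.occ.sum())

    def check_occupancy(self) -> None:
        for r in range(self.n_rows):
            live = self.grid[r, : self.caps[r]]
            ids = live[live >= 0]
            assert len(ids) == len(set(ids.tolist())) == self.occ[r]


def place_daughter(
    lattice: Lattice,
    origin_row: int,
    origin_slot: int,
    cell_id: int,
    *,
    seed: int = 0,
    force_forward: bool = False,
) -> dict:
    """Insert ``cell_id`` next to (origin_row, origin_slot) under the
    movement rules; returns the row-changing moves and the exited cell (if
    any).  Thin wrapper over the kernel used by the simulations."""
    total = int(lattice.caps.sum())
    moved = np.empty(10 * total + 128, dtype=np.int64)
    moved_old = np.empty_like(moved)
    _kernels.seed_rng(seed)
    nm, exited = _kernels._place(
        lattice.grid, lattice.occ, lattice.caps, lattice.n_rows,
        cell_id, origin_row, origin_slot,
        lattice.row_of, lattice.slot_of, force_forward, moved, moved_old,
    )
    if nm < 0:
        raise RuntimeError("displacement chain exceeded total MZ capacity")
    return {
        "moved": [(int(moved[k]), int(moved_old[k]), int(lattice.row_of[moved[k]]))
                  for k in range(nm)],
        "exited": int(exited) if exited >= 0 else None,
    }


def _premeiosis_arrays(
    config: SimulationConfig, profile: CellCycleProfile, n_rows: int
) -> tuple[int, int, np.ndarray, np.ndarray]:
    """(flag, pmz_start_0based, frac_cum, exp_m_index) for the kernels."""
    if not config.premeiosis:
        return 0, n_rows, np.zeros((n_rows, 3)), np.zeros(n_rows)
    mi = np.asarray(config.mitotic_index_profile, dtype=np.float64)
    if mi.size != n_rows:
        raise ValueError("mitotic-index profile must cover every row")
    fr = profile.fractions_table(n_rows)
    frac_cum = np.cumsum(fr[:, :3], axis=1)
    # the PMZ starts where the experimental profile is first flagged (< 0
    # marks rows without premeiotic entry); by convention the caller encodes
    # the PMZ as the trailing rows with finite indices
    pmz_start = 0
    for r in range(n_rows):
        if mi[r] < np.inf:
            pmz_start = r
            break
    return 1, pmz_start, frac_cum, np.where(np.isfinite(mi), mi, 1.0)


def _frac_cum_for(profile: CellCycleProfile, n_rows: int) -> np.ndarray:
    fr = profile.fractions_table(n_rows)
    return np.cumsum(fr[:, :3], axis=1)


def run_mutation_accumulation(
    config: SimulationConfig,
    geometry: MZGeometry,
    profile: CellCycleProfile,
    apoptosis: ApoptosisProfile | None = None,
    schedule: ProductionSchedule | None = None,
    queue: MeioticQueue | None = None,
    *,
    n_exits: int | None = 3000,
    n_pop: int | None = None,
    max_divisions: int | None = None,
) -> SimulationResult:
    """Seed one progenitor distally and simulate until ``n_exits`` cells have
    left the MZ (or the MZ population reaches ``n_pop``).

    The developmental clock is the cumulative division count; it drives the
    cycle profile, the geometry interpolation, and the apoptosis profile.
    Wall-clock hours drive only the production schedule.
    """
    n_rows = geometry.n_rows
    geo_anchors, geo_table = geometry.as_arrays()
    cp_rows, anchors, lengths = profile.as_arrays()
    max_cells_lat = geometry.max_cells
    if n_pop is None:
        n_pop = max_cells_lat + 10  # unreachable: lattice caps the population
    if n_exits is None:
        # stop on population size only; exits are bounded by the run length
        if max_divisions is None:
            max_divisions = n_pop + max_cells_lat + 64
        n_exits = max_divisions
    if max_divisions is None:
        max_divisions = n_exits + max_cells_lat + max(n_pop, 0) + 64

    ncell = max_divisions + 2
    row = np.full(ncell, -2, dtype=np.int64)
    slot = np.zeros(ncell, dtype=np.int64)
    depth = np.zeros(ncell, dtype=np.float64)
    tdiv = np.full(ncell, INF, dtype=np.float64)
    tau = np.ones(ncell, dtype=np.float64)
    tg2 = np.full(ncell, INF, dtype=np.float64)
    g2done = np.zeros(ncell, dtype=np.int64)
    active = np.zeros(min(ncell, max(max_cells_lat, n_pop) + 16), dtype=np.int64)
    wmax = int(geo_table.max())
    lat = np.full((n_rows, wmax), -1, dtype=np.int64)
    occ = np.zeros(n_rows, dtype=np.int64)
    caps = np.zeros(n_rows, dtype=np.int64)
    moved = np.empty(10 * n_rows * wmax + 128, dtype=np.int64)
    moved_old = np.empty_like(moved)
    row_len = np.zeros(n_rows, dtype=np.float64)
    exit_cell = np.zeros(max_divisions + 2, dtype=np.int64)
    exit_depth = np.zeros(max_divisions + 2, dtype=np.float64)
    exit_time = np.zeros(max_divisions + 2, dtype=np.float64)
    exit_clock = np.zeros(max_divisions + 2, dtype=np.float64)
    div_times = np.zeros(max_divisions + 2, dtype=np.float64)
    pop_depth = np.zeros(ncell, dtype=np.float64)

    pm_flag, pmz_start, frac_cum, exp_mi = _premeiosis_arrays(config, profile, n_rows)

    n_ex, ndiv, n_cells, npop = _kernels.run_ma(
        int(config.seed) & 0x7FFFFFFF,
        n_rows, caps, geo_anchors, geo_table, 1 if geometry.is_static else 0,
        cp_rows, anchors, lengths, profile.min_cycle_length,
        config.division_jitter, VARIANTS[config.pedigree_variant],
        pm_flag, pmz_start, frac_cum, exp_mi,
        n_exits, n_pop, max_divisions,
        row, slot, depth, tdiv, tau, tg2, g2done,
        active, lat, occ, moved, moved_old, row_len,
        exit_cell, exit_depth, exit_time, exit_clock, div_times,
        pop_depth,
    )
    if n_ex < 0:
        raise RuntimeError("displacement chain exceeded total MZ capacity")

    exits = pd.DataFrame(
        {
            "exit_index": np.arange(1, n_ex + 1),
            "pedigree_depth": exit_depth[:n_ex].copy(),
            "exit_clock": exit_clock[:n_ex].copy(),
            "exit_time_h": exit_time[:n_ex].copy(),
        }
    )
    sperm_times = np.empty(0)
    oocyte_times = np.empty(0)
    if apoptosis is not None:
        rng = np.random.default_rng((int(config.seed) * 2654435761 + 17) & 0x7FFFFFFF)
        acc = assign_gamete_fates(
            exits["exit_time_h"].to_numpy(),
            exits["exit_clock"].to_numpy(),
            apoptosis, rng, schedule=schedule, queue=queue,
        )
        exits["fate"] = acc.fates
        sperm_times = acc.sperm_times
        oocyte_times = acc.oocyte_times
    else:
        exits["fate"] = "unassigned"

    return SimulationResult(
        exits=exits,
        divisions=ndiv,
        div_times_h=div_times[:ndiv].copy(),
        mz_depths=pop_depth[:npop].copy(),
        sperm_times_h=sperm_times,
        oocyte_times_h=oocyte_times,
    )


def run_pulse_chase(
    config: SimulationConfig,
    geometry: MZGeometry,
    profile: CellCycleProfile,
    chase_times: Sequence[float] | None = None,
    *,
    arm_id: int = 0,
) -> pd.DataFrame:
    """Simulate an EdU pulse-chase on one gonadal arm.

    The MZ starts pre-filled with an asynchronous population whose cell ages
    follow the exponential density with f(0) = 2 f(1); after a pre-run
    (default 2 h) S-phase cells are marked EdU-positive; snapshots of every
    cell's (row, phase, theoretical DNA content, EdU flag) are taken at each
    chase time.  Cycle parameters stay constant over the run.

    Returns a tidy frame: arm_id, chase_h, row (1-based), phase, dna_c, edu,
    m_flag.
    """
    if not profile.phase_fractions:
        raise ValueError("pulse-chase simulations need phase fractions")
    chase = np.asarray(
        sorted(config.chase_times_h if chase_times is None else chase_times),
        dtype=np.float64,
    )
    if chase.size and chase.max() > 8.0:
        import warnings

        warnings.warn("chase times beyond 8 h are outside the calibrated regime")

    n_rows = geometry.n_rows
    caps = geometry.capacities_at(0.0).astype(np.int64)
    cp_rows, anchors, lengths = profile.as_arrays()
    frac_cum = _frac_cum_for(profile, n_rows)
    pm_flag, pmz_start, _, exp_mi = _premeiosis_arrays(config, profile, n_rows)

    total = int(caps.sum())
    dur = config.pre_run_h + (chase.max() if chase.size else 0.0)
    min_len = profile.min_length_over(n_rows, 0.0)
    ncell = int(total * (dur / max(min_len, 1e-6) + 3) * 2) + total + 64
    row = np.full(ncell, -2, dtype=np.int64)
    slot = np.zeros(ncell, dtype=np.int64)
    tdiv = np.full(ncell, INF, dtype=np.float64)
    tau = np.ones(ncell, dtype=np.float64)
    tg2 = np.full(ncell, INF, dtype=np.float64)
    g2done = np.zeros(ncell, dtype=np.int64)
    edu = np.zeros(ncell, dtype=np.int64)
    arrested = np.zeros(ncell, dtype=np.int64)
    active = np.zeros(total + 16, dtype=np.int64)
    lat = np.full((n_rows, int(caps.max())), -1, dtype=np.int64)
    occ = np.zeros(n_rows, dtype=np.int64)
    moved = np.empty(10 * total + 128, dtype=np.int64)
    moved_old = np.empty_like(moved)
    row_len = np.zeros(n_rows, dtype=np.float64)
    nc = chase.size
    out_count = np.zeros(nc, dtype=np.int64)
    out_row = np.zeros((nc, total + 16), dtype=np.int64)
    out_phase = np.zeros((nc, total + 16), dtype=np.int64)
    out_dna = np.zeros((nc, total + 16), dtype=np.float64)
    out_edu = np.zeros((nc, total + 16), dtype=np.int64)

    res = _kernels.run_pc_kernel(
        int(config.seed) & 0x7FFFFFFF,
        n_rows, caps,
        cp_rows, anchors, lengths, profile.min_cycle_length,
        config.division_jitter, frac_cum,
        pm_flag, pmz_start, exp_mi,
        config.pre_run_h, chase,
        row, slot, tdiv, tau, tg2, g2done, edu, arrested,
        active, lat, occ, moved, moved_old, row_len,
        out_count, out_row, out_phase, out_dna, out_edu,
    )
    if res < 0:
        raise RuntimeError("displacement chain exceeded total MZ capacity")

    frames = []
    for i, tc in enumerate(chase):
        k = out_count[i]
        frames.append(
            pd.DataFrame(
                {
                    "arm_id": arm_id,
                    "chase_h": tc,
                    "row": out_row[i, :k] + 1,
                    "phase": PHASE_NAMES[out_phase[i, :k]],
                    "dna_c": out_dna[i, :k],
                    "edu": out_edu[i, :k].astype(np.int64),
                    "m_flag": (out_phase[i, :k] == _kernels.PH_M).astype(np.int64),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
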