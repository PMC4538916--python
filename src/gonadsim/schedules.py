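"""Meiotic-zone bookkeeping: apoptosis profile, production schedule, FIFO.

Cells leaving the mitotic zone (MZ) enter the meiotic zone (MeZ), a
first-in-first-out queue.  The first 44 entrants are drawn for primary
spermatocytes during larval development; afterwards, oocyte maturation pops
cells from the proximal end, each popped cell undergoing apoptosis with a
probability that depends on its MZ-exit sequence index (so that the apoptosis
profile, like every other simulation input except the production schedule, is
defined on the developmental clock of cumulative divisions rather than on
elapsed time).

Oocyte maturation is demand-driven on the experimentally measured
reproductive schedule (wall-clock hours), gated by supply: an oocyte can only
be pushed out once the MeZ has grown to its stage-interpolated size, which is
what delays reproduction when germ cells cycle slowly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ApoptosisProfile",
    "ProductionWindow",
    "ProductionSchedule",
    "MeioticQueue",
    "GameteAccounting",
]


@dataclass(frozen=True)
class ApoptosisProfile:
    """Apoptosis probability of MeZ leavers by MZ-exit sequence index.

    ``breakpoints`` are the inclusive upper indices of the first bands;
    ``probabilities`` has one more entry than ``breakpoints`` (the last band
    is open-ended).  Primary spermatocytes (the first 44 entrants) are exempt.
    """

    breakpoints: tuple[int, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.probabilities) != len(self.breakpoints) + 1:
            raise ValueError("need one probability per band (last band open)")
        if any(not 0.0 <= p <= 1.0 for p in self.probabilities):
            raise ValueError("probabilities must lie in [0, 1]")
        if list(self.breakpoints) != sorted(set(self.breakpoints)):
            raise ValueError("breakpoints must be strictly increasing")

    @classmethod
    def zero(cls) -> "ApoptosisProfile":
        return cls((), (0.0,))

    def probability(self, exit_index: int) -> float:
        """Apoptosis probability for the 1-based MZ-exit index."""
        if exit_index < 1:
            raise ValueError("exit indices are 1-based")
        for b, p in zip(self.breakpoints, self.probabilities):
            if exit_index <= b:
                return p
        return self.probabilities[-1]

    def probabilities_for(self, n: int) -> np.ndarray:
        idx = np.arange(1, n + 1)
        out = np.full(n, self.probabilities[-1])
        prev = 0
        for b, p in zip(self.breakpoints, self.probabilities):
            out[(idx > prev) & (idx <= b)] = p
            prev = b
        return out


@dataclass(frozen=True)
class ProductionWindow:
    t_start_h: float
    t_end_h: float
    gamete: str  # "sperm" | "oocyte"
    count: int


@dataclass(frozen=True)
class ProductionSchedule:
    """Gamete-production windows (wall-clock) plus division checkpoints.

    Checkpoints are (hours, cumulative divisions) pairs: the developmental
    clock must have advanced at least that far by that time.
    """

    windows: tuple[ProductionWindow, ...]
    checkpoints: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        for w in self.windows:
            if w.count < 0 or w.t_end_h <= w.t_start_h:
                raise ValueError("windows need count >= 0 and positive span")

    @property
    def sperm_target(self) -> int:
        return sum(w.count for w in self.windows if w.gamete == "sperm")

    @property
    def oocyte_target(self) -> int:
        return sum(w.count for w in self.windows if w.gamete == "oocyte")

    def demand_times(self, gamete: str) -> np.ndarray:
        """Scheduled production times, spread uniformly within each window."""
        times: list[float] = []
        for w in self.windows:
            if w.gamete != gamete or w.count == 0:
                continue
            span = w.t_end_h - w.t_start_h
            times.extend(w.t_start_h + span * (j + 1) / w.count for j in range(w.count))
        return np.asarray(sorted(times))

    def cumulative_demand(self, gamete: str, t: float) -> int:
        return int(np.searchsorted(self.demand_times(gamete), t, side="right"))


@dataclass(frozen=True)
class MeioticQueue:
    """FIFO meiotic zone with a stage-interpolated size.

    ``size_anchors`` maps developmental-clock values to MeZ cell numbers;
    linear in between, clamped outside.
    """

    size_anchors: tuple[tuple[float, float], ...]

    def capacity(self, clock: float) -> float:
        ks = np.array([a[0] for a in self.size_anchors])
        vs = np.array([a[1] for a in self.size_anchors])
        return float(np.interp(clock, ks, vs))


@dataclass
class GameteAccounting:
    """Fates and release times for an ordered stream of MZ exits."""

    fates: np.ndarray          # object array: sperm|oocyte|apoptosis|unassigned
    sperm_times: np.ndarray    # release (production) times of spermatocytes
    oocyte_times: np.ndarray   # release times of matured oocytes
    oocyte_indices: np.ndarray  # 1-based MZ-exit indices of the oocytes


def assign_gamete_fates(
    exit_time: np.ndarray,
    exit_clock: np.ndarray,
    apoptosis: ApoptosisProfile,
    rng: np.random.Generator,
    *,
    schedule: ProductionSchedule | None = None,
    queue: MeioticQueue | None = None,
    sperm_target: int = 44,
    oocyte_target: int = 176,
) -> GameteAccounting:
    """Assign sperm/oocyte/apoptosis fates to MZ exits, in FIFO order.

    Without a schedule, fates depend only on the exit sequence index (the
    first ``sperm_target`` exits are primary spermatocytes; later leavers
    survive apoptosis with the index-band probability until ``oocyte_target``
    oocytes exist) and release times equal entry times.  With a schedule and
    queue, oocyte releases additionally wait for their scheduled demand time
    and for the MeZ to have filled to its stage-interpolated size.
    """
    n = len(exit_time)
    fates = np.array(["unassigned"] * n, dtype=object)
    if schedule is not None:
        sperm_target = schedule.sperm_target or sperm_target
        oocyte_target = schedule.oocyte_target or oocyte_target

    n_sperm = min(sperm_target, n)
    fates[:n_sperm] = "sperm"
    if schedule is not None:
        sperm_demand = schedule.demand_times("sperm")
        sperm_times = np.maximum(sperm_demand[:n_sperm], exit_time[:n_sperm])
    else:
        sperm_times = exit_time[:n_sperm].copy()

    # apoptosis draws, one per potential leaver beyond the spermatocytes
    p = apoptosis.probabilities_for(n)
    survives = rng.random(n) >= p
    survives[:n_sperm] = True

    ooc_times: list[float] = []
    ooc_idx: list[int] = []
    q = n_sperm  # number of cells popped from the queue so far

    if schedule is None or queue is None:
        for i in range(n_sperm, n):
            if len(ooc_idx) >= oocyte_target:
                break
            if survives[i]:
                fates[i] = "oocyte"
                ooc_times.append(exit_time[i])
                ooc_idx.append(i + 1)
            else:
                fates[i] = "apoptosis"
        return GameteAccounting(fates, sperm_times, np.asarray(ooc_times),
                                np.asarray(ooc_idx))

    demand = schedule.demand_times("oocyte")
    for tau in demand[:oocyte_target]:
        # next surviving cell in FIFO order
        m = q
        while m < n and not survives[m]:
            m += 1
        if m >= n:
            break  # supply exhausted: reproduction ends early
        # earliest time >= tau when the m+1-th entrant exists and the MeZ has
        # filled to its interpolated size (pre-pop occupancy >= capacity)
        e = m + 1  # entrants needed so the survivor is in the queue
        released = False
        while e <= n:
            t_cand = max(tau, exit_time[e - 1])
            e_eff = int(np.searchsorted(exit_time, t_cand, side="right"))
            cap = queue.capacity(exit_clock[e_eff - 1])
            if e_eff - q >= cap:
                for i in range(q, m):
                    fates[i] = "apoptosis"
                fates[m] = "oocyte"
                ooc_times.append(t_cand)
                ooc_idx.append(m + 1)
                q = m + 1
                released = True
                break
            e = e_eff + 1
        if not released:
            break  # the MeZ never refills: no further oocytes
    return GameteAccounting(fates, sperm_times, np.asarray(ooc_times),
                            np.asarray(ooc_idx))
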