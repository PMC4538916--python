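"""Population growth rate from reproductive schedules, and the fitness that
trades off growth-rate changes against replication-dependent mutation load.

The reproductive schedule of a simulated gonadal arm (progeny birth times
since egg laying, with embryonic and larval development assumed to proceed at
constant speed) is binned into fixed age classes and assembled into an
age-structured (Leslie) transition matrix with unit survival through the
reproductive span.  The population growth rate is r = ln(d) per step, where d
is the dominant eigenvalue; for N progeny all produced at age g this reduces
to the Euler-Lotka closed form r = ln(N)/g.

Fitness of a variant (p, r) against a reference (p0, r0) with genome-wide
deleterious mutation rate U per generation:

    dU  = U (p - p0) / p0          (all mutations replication-dependent)
    s_U = -dU / 2                  (selfing)
    ln(1 + s_G) = (r - r0)/r0 * ln(N)
    fitness = 1 + s_U + s_G
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ReproductiveSchedule",
    "FitnessParams",
    "leslie_matrix",
    "growth_rate",
    "doubling_time",
    "fitness",
]


@dataclass(frozen=True)
class ReproductiveSchedule:
    """Progeny birth times (hours since egg laying of the parent), with
    per-event weights so schedules averaged over replicate simulations keep
    fractional counts."""

    times_h: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if t.size == 0:
            raise ValueError("schedule has no progeny")
        if np.any(t < 0) or np.any(np.diff(t) < 0):
            raise ValueError("times must be nonnegative and sorted")
        if w.shape != t.shape or np.any(w < 0):
            raise ValueError("need one nonnegative weight per time")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "weights", w)

    @property
    def total_progeny(self) -> float:
        return float(self.weights.sum())

    @classmethod
    def from_times(cls, times_h: Sequence[float]) -> "ReproductiveSchedule":
        t = np.sort(np.asarray(times_h, dtype=float))
        return cls(t, np.ones_like(t))

    @classmethod
    def averaged(
        cls,
        replicate_times: Iterable[Sequence[float]],
        offset_h: float = 0.0,
    ) -> "ReproductiveSchedule":
        """Average schedule over replicate runs: pooled event times with
        weight 1/replicates each, shifted by ``offset_h`` (e.g. the egg-laying
        to simulation-origin offset)."""
        reps = [np.asarray(t, dtype=float) + offset_h for t in replicate_times]
        if not reps:
            raise ValueError("no replicate schedules given")
        n = len(reps)
        allt = np.sort(np.concatenate(reps))
        return cls(allt, np.full(allt.size, 1.0 / n))


def _fertilities(schedule: ReproductiveSchedule, step_h: float) -> np.ndarray:
    """Per-age-class fertility: ``fert[a]`` = offspring produced at age
    a*step_h (nearest age class)."""
    idx = np.rint(schedule.times_h / step_h).astype(int)
    n_bins = int(idx.max()) + 1
    fert = np.zeros(n_bins)
    np.add.at(fert, idx, schedule.weights)
    return fert


def leslie_matrix(fertilities: np.ndarray) -> np.ndarray:
    """Age-structured transition matrix for ``fert[a]`` = offspring at age a
    (in steps): unit survival on the subdiagonal through the reproductive
    span, with the birth row placed so the characteristic equation is the
    Euler-Lotka relation  sum_a fert[a] lambda^-a = 1  (an individual of age
    a-1 produces fert[a] newborns during the step in which it turns a)."""
    f = np.asarray(fertilities, dtype=float)
    if f.size < 2 or f[0] != 0:
        raise ValueError("fertility at age 0 is not representable")
    a = f.size - 1
    m = np.zeros((a, a))
    m[0, :] = f[1:]
    for i in range(a - 1):
        m[i + 1, i] = 1.0
    return m


def growth_rate(schedule: ReproductiveSchedule, step_h: float = 1.0) -> float:
    """Exponential growth rate r (per hour) = ln(dominant eigenvalue) of the
    transition matrix built from the binned schedule."""
    if schedule.total_progeny <= 0:
        raise ValueError("schedule with zero progeny: growth rate undefined")
    fert = _fertilities(schedule, step_h)
    m = leslie_matrix(fert)
    eig = np.linalg.eigvals(m)
    lam = float(np.max(eig.real))
    if lam <= 0:
        raise ValueError("no positive dominant eigenvalue")
    return float(np.log(lam) / step_h)


def doubling_time(r: float) -> float:
    """Population doubling time ln(2)/r, in hours for r per hour."""
    if r <= 0:
        raise ValueError("doubling time needs r > 0")
    return float(np.log(2.0) / r)


@dataclass(frozen=True)
class FitnessParams:
    """Inputs to the growth/mutation-load fitness."""

    U: float      # deleterious mutation rate per generation
    p0: float     # reference pedigree depth
    r0: float     # reference growth rate
    p: float      # candidate pedigree depth
    r: float      # candidate growth rate
    N: float      # progeny per generation (for ln(N))

    def __post_init__(self) -> None:
        if self.U < 0:
            raise ValueError("U must be >= 0")
        if self.p0 <= 0 or self.p <= 0:
            raise ValueError("pedigree depths must be positive")
        if self.r0 == 0:
            raise ValueError("reference growth rate must be nonzero")
        if self.N <= 0:
            raise ValueError("progeny count must be positive")


def fitness(params: FitnessParams) -> float:
    """1 + s_U + s_G (see module docstring)."""
    s_u = -params.U * (params.p - params.p0) / (2.0 * params.p0)
    s_g = np.exp((params.r - params.r0) / params.r0 * np.log(params.N)) - 1.0
    return float(1.0 + s_u + s_g)
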