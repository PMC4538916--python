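"""Domain types shared across the simulation and fitting modules.

The mitotic zone (MZ) of a *C. elegans* gonadal arm is modelled as a
cylindrical lattice: a long (distal--proximal) axis of cell rows and a short
circular axis of slots per row.  Cell-cycle length is a piecewise-linear
function of row position and of the developmental clock, which is measured in
cumulative germ-cell divisions (not wall-clock hours) so that simulation
inputs are invariant under a global rescaling of cycling speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MZGeometry",
    "CellCycleProfile",
    "interpolate_cycle_length",
    "interpolate_geometry",
    "PHASES",
]

#: Cell-cycle phases in temporal order.
PHASES = ("G1", "S", "G2", "M")


def _interp_clamped(x: float, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Linear interpolation in ``x`` over anchors ``xs``, clamped outside."""
    if x <= xs[0]:
        return ys[0]
    if x >= xs[-1]:
        return ys[-1]
    i = int(np.searchsorted(xs, x, side="right")) - 1
    w = (x - xs[i]) / (xs[i + 1] - xs[i])
    return ys[i] * (1.0 - w) + ys[i + 1] * w


@dataclass(frozen=True)
class MZGeometry:
    """Lattice shape of the mitotic zone, optionally varying with the clock.

    Parameters
    ----------
    control_stages
        Developmental-clock anchors (cumulative divisions), strictly
        increasing.  A single anchor means a constant geometry.
    row_capacities
        For each anchor, the number of cells per row from the distal row 1 to
        the most proximal row.  All anchors must list the same number of rows.
    wraparound
        Rows are circular along the short axis (cone-like gonad shape); kept
        as a flag for documentation, the movement rules always wrap.
    """

    control_stages: tuple[float, ...]
    row_capacities: tuple[tuple[int, ...], ...]
    wraparound: bool = True

    def __post_init__(self) -> None:
        if not self.row_capacities:
            raise ValueError("geometry needs at least one capacity anchor")
        stages = np.asarray(self.control_stages, dtype=float)
        if stages.size != len(self.row_capacities):
            raise ValueError("one capacity list per control stage required")
        if stages.size > 1 and not np.all(np.diff(stages) > 0):
            raise ValueError("control stages must be strictly increasing")
        n_rows = {len(c) for c in self.row_capacities}
        if len(n_rows) != 1:
            raise ValueError("all anchors must define the same number of rows")
        for caps in self.row_capacities:
            if len(caps) == 0 or any(c < 1 for c in caps):
                raise ValueError("row capacities must be >= 1 and nonempty")

    @classmethod
    def rectangular(cls, length: int, width: int) -> "MZGeometry":
        """Constant rectangular lattice: ``length`` rows of ``width`` cells."""
        return cls((0.0,), (tuple([int(width)] * int(length)),))

    @property
    def n_rows(self) -> int:
        return len(self.row_capacities[0])

    @property
    def is_static(self) -> bool:
        return len(self.control_stages) == 1

    @property
    def max_cells(self) -> int:
        return int(max(sum(c) for c in self.row_capacities))

    def capacities_at(self, clock: float) -> np.ndarray:
        """Per-row capacities at a developmental clock, rounded to integers."""
        stages = np.asarray(self.control_stages, dtype=float)
        table = np.asarray(self.row_capacities, dtype=float)
        caps = _interp_clamped(float(clock), stages, table)
        return np.maximum(np.rint(caps).astype(np.int64), 1)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.asarray(self.control_stages, dtype=np.float64),
            np.asarray(self.row_capacities, dtype=np.float64),
        )


def interpolate_geometry(geometry: MZGeometry, clock: float) -> np.ndarray:
    """Per-row capacities at ``clock`` (linear in clock, clamped, rounded)."""
    if clock < 0:
        raise ValueError("clock must be >= 0")
    return geometry.capacities_at(clock)


@dataclass(frozen=True)
class CellCycleProfile:
    """Piecewise-linear total cell-cycle length over (row, clock).

    ``control_rows`` are 1-based row indices (row 1 = distal end); lengths are
    bilinear between control points: linear along the row axis between spatial
    control points and linear along the developmental clock between stage
    anchors, clamped to the nearest anchor outside the anchored range, and
    never below ``min_cycle_length``.

    ``phase_fractions`` maps an inclusive 1-based row range to the relative
    lengths of (G1, S, G2, M); it is only needed by pulse-chase simulations
    and by pre-meiotic arrest, which track phase progression.
    """

    control_rows: tuple[int, ...]
    anchors: tuple[float, ...]
    lengths: tuple[tuple[float, ...], ...]
    min_cycle_length: float = 2.8
    phase_fractions: tuple[tuple[int, int, tuple[float, float, float, float]], ...] = ()

    def __post_init__(self) -> None:
        if len(self.control_rows) == 0:
            raise ValueError("profile needs at least one spatial control point")
        if list(self.control_rows) != sorted(set(self.control_rows)):
            raise ValueError("control rows must be strictly increasing")
        anchors = np.asarray(self.anchors, dtype=float)
        if anchors.size != len(self.lengths):
            raise ValueError("one length row per clock anchor required")
        if anchors.size > 1 and not np.all(np.diff(anchors) > 0):
            raise ValueError("clock anchors must be strictly increasing")
        for row_vals in self.lengths:
            if len(row_vals) != len(self.control_rows):
                raise ValueError("each anchor needs one length per control row")
            if any(v < self.min_cycle_length - 1e-9 for v in row_vals):
                raise ValueError(
                    f"cycle lengths must be >= min_cycle_length={self.min_cycle_length}"
                )
        for lo, hi, fracs in self.phase_fractions:
            f = np.asarray(fracs, dtype=float)
            if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-6:
                raise ValueError("phase fractions must be nonnegative and sum to 1")
            if lo > hi:
                raise ValueError("phase-fraction row range inverted")

    @classmethod
    def flat(
        cls,
        length_h: float,
        *,
        min_cycle_length: float | None = None,
        anchors: Sequence[float] = (0.0,),
        lengths_by_anchor: Sequence[float] | None = None,
        phase_fractions: Mapping[tuple[int, int], Sequence[float]] | None = None,
    ) -> "CellCycleProfile":
        """Spatially flat profile, optionally varying with the clock."""
        vals = lengths_by_anchor if lengths_by_anchor is not None else [length_h] * len(anchors)
        mcl = min(vals) if min_cycle_length is None else min_cycle_length
        pf = tuple(
            (lo, hi, tuple(float(x) for x in fr))
            for (lo, hi), fr in (phase_fractions or {}).items()
        )
        return cls(
            control_rows=(1,),
            anchors=tuple(float(a) for a in anchors),
            lengths=tuple((float(v),) for v in vals),
            min_cycle_length=float(mcl),
            phase_fractions=pf,
        )

    @classmethod
    def gradient(
        cls,
        distal_h: float,
        proximal_h: float,
        n_rows: int,
        *,
        min_cycle_length: float | None = None,
        phase_fractions: Mapping[tuple[int, int], Sequence[float]] | None = None,
    ) -> "CellCycleProfile":
        """Two-control-point linear gradient from row 1 to row ``n_rows``."""
        mcl = min(distal_h, proximal_h) if min_cycle_length is None else min_cycle_length
        pf = tuple(
            (lo, hi, tuple(float(x) for x in fr))
            for (lo, hi), fr in (phase_fractions or {}).items()
        )
        return cls(
            control_rows=(1, int(n_rows)),
            anchors=(0.0,),
            lengths=((float(distal_h), float(proximal_h)),),
            min_cycle_length=float(mcl),
            phase_fractions=pf,
        )

    def length(self, row: int, clock: float) -> float:
        """Total cycle length (hours) at 1-based ``row`` and clock."""
        anchors = np.asarray(self.anchors, dtype=float)
        table = np.asarray(self.lengths, dtype=float)
        at_clock = _interp_clamped(float(clock), anchors, table)
        rows = np.asarray(self.control_rows, dtype=float)
        val = float(_interp_clamped(float(row), rows, at_clock))
        return max(val, self.min_cycle_length)

    def fractions_for_row(self, row: int) -> tuple[float, float, float, float]:
        for lo, hi, fr in self.phase_fractions:
            if lo <= row <= hi:
                return fr
        raise KeyError(f"no phase fractions configured for row {row}")

    def fractions_table(self, n_rows: int) -> np.ndarray:
        """(n_rows, 4) phase-fraction table for the kernels (1-based rows)."""
        out = np.empty((n_rows, 4), dtype=np.float64)
        for r in range(1, n_rows + 1):
            out[r - 1] = self.fractions_for_row(r)
        return out

    def min_length_over(self, n_rows: int, clock: float) -> float:
        """Minimum cycle length over rows 1..n_rows at ``clock``."""
        cand = [1, n_rows] + [r for r in self.control_rows if 1 <= r <= n_rows]
        return min(self.length(r, clock) for r in cand)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            np.asarray(self.control_rows, dtype=np.float64) - 1.0,  # 0-based for kernels
            np.asarray(self.anchors, dtype=np.float64),
            np.asarray(self.lengths, dtype=np.float64),
        )


def interpolate_cycle_length(profile: CellCycleProfile, row: int, clock: float) -> float:
    """Bilinear cycle-length lookup; see :meth:`CellCycleProfile.length`."""
    if clock < 0:
        raise ValueError("clock must be >= 0")
    return profile.length(row, clock)
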