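"""Every input the pipeline consumes, generated or tabulated in-code.

Two kinds of objects live here:

* fixture tables that parameterize the biology — the apoptosis probabilities
  by meiotic-zone exit index, the measured reproductive schedule with its
  division-count checkpoints, stage timings on the developmental clock, MeZ
  size anchors, compartment boundaries, cycling-speed limits, and a cone-like
  stand-in geometry matching the printed mean gonad dimensions (19.3 rows
  long, 13.5 cells wide on average; the full row-by-row measurements are not
  reproduced here);

* synthetic pulse-chase datasets with known ground truth, wrapping the
  lattice simulator and adding per-cell measurement noise (multiplicative
  lognormal intensity noise on DNA content, EdU misclassification), so that
  the fitting machinery can be exercised end to end without microscopy data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .lattice_simulator import (
    SimulationConfig,
    run_mutation_accumulation,
    run_pulse_chase,
)
from .profiles import CellCycleProfile, MZGeometry
from .schedules import ApoptosisProfile, MeioticQueue, ProductionSchedule, ProductionWindow

__all__ = [
    "FixtureSet",
    "SyntheticSpec",
    "load_fixtures",
    "default_truth_profile",
    "fitting_geometry",
    "generate_pulse_chase",
    "generate_toy_tree_scenarios",
]

#: Relative phase lengths (G1, S, G2, M) used as synthetic defaults: germ
#: cells spend almost no time in G1 and most of the cycle in S and G2.
DEFAULT_PHASE_FRACTIONS = (0.07, 0.50, 0.40, 0.03)

#: Cycling-speed limits (hours): the fastest observed cycles are 3.4 h during
#: early larval development (L2-L3) and 2.8 h from L4 onwards.
SPEED_LIMITS = {"pre_L4": 3.4, "post_L4": 2.8}

#: Developmental-stage anchors: (cumulative divisions, hours since the onset
#: of germ-line proliferation).  Egg laying precedes that onset by 24 h, and
#: mid-L4 is reached 54 h after egg laying.
STAGE_CLOCKS = {"onset": (0, 0.0), "L4": (400, 30.0), "L4+1": (1200, 54.0),
                "L4+3": (2400, 102.0)}
EGG_TO_ONSET_H = 24.0
EGG_TO_L4_H = 54.0

#: DMMZ / MMZ row spans (1-based, inclusive) per stage.
COMPARTMENTS = {
    "L4": {"DMMZ": (1, 8), "MMZ": (9, 15)},
    "L4+1": {"DMMZ": (1, 6), "MMZ": (7, 11)},
}


@dataclass(frozen=True)
class FixtureSet:
    """In-code copies of the parameter tables driving the simulations."""

    apoptosis: ApoptosisProfile
    schedule: ProductionSchedule
    meiotic_queue: MeioticQueue
    stage_clocks: Mapping[str, tuple[int, float]]
    compartments: Mapping[str, Mapping[str, tuple[int, int]]]
    speed_limits: Mapping[str, float]
    geometry: MZGeometry


def load_fixtures() -> FixtureSet:
    """Fixture tables: apoptosis by exit index, production schedule with
    division checkpoints, MeZ size anchors, stage timings, compartment
    boundaries, speed limits, and the cone-like stand-in geometry."""
    apoptosis = ApoptosisProfile(
        breakpoints=(210, 682, 1150, 1478),
        probabilities=(0.68, 0.83, 0.86, 0.98, 0.99),
    )
    # Division-count checkpoints enforce the experimentally observed speed of
    # development.  The counts are not directly measurable; like the stage
    # clock itself they are calibrated by simulating the reference
    # experimental-speed profile and reading off the cumulative divisions at
    # the measured stage times (see calibrate_stage_clocks); the values below
    # are that calibration for this simulator.
    # The spermatogenesis deadline is calibrated the same way (time at which
    # the reference simulation has pushed its first 44 cells into the MeZ).
    schedule = ProductionSchedule(
        windows=(
            ProductionWindow(0.0, 31.3, "sperm", 44),
            ProductionWindow(30.0, 54.0, "oocyte", 23),
            ProductionWindow(54.0, 78.0, "oocyte", 83),
            ProductionWindow(78.0, 102.0, "oocyte", 64),
            ProductionWindow(102.0, 126.0, "oocyte", 5),
            ProductionWindow(126.0, 150.0, "oocyte", 1),
        ),
        checkpoints=((30.0, 255.0), (54.0, 1236.0), (102.0, 2753.0)),
    )
    queue = MeioticQueue(size_anchors=((400.0, 500.0), (1200.0, 749.0),
                                       (2400.0, 1077.0)))
    # cone-like stand-in: 19 rows, widths tapering 12 -> 15 (mean 13.5)
    widths = tuple(int(round(12 + 3 * r / 18)) for r in range(19))
    geometry = MZGeometry((0.0,), (widths,))
    return FixtureSet(
        apoptosis=apoptosis,
        schedule=schedule,
        meiotic_queue=queue,
        stage_clocks=STAGE_CLOCKS,
        compartments=COMPARTMENTS,
        speed_limits=SPEED_LIMITS,
        geometry=geometry,
    )


def reference_experimental_profile() -> CellCycleProfile:
    """Stand-in for the experimentally fitted cycle profile: a flat 3.4 h
    early-larval cycle developing into an approximately twofold
    distal-proximal gradient from L4 onwards."""
    return CellCycleProfile(
        control_rows=(1, 19),
        anchors=(0.0, 400.0, 1200.0, 2400.0),
        lengths=((3.4, 3.4), (6.0, 2.8), (8.0, 4.0), (8.0, 4.0)),
        min_cycle_length=2.8,
    )


def calibrate_stage_clocks(seed: int = 0, replicates: int = 30) -> dict[float, int]:
    """Cumulative divisions reached at the measured stage times (30/54/102 h)
    when germ cells cycle on the reference experimental-speed profile.

    This reproduces the calibration that defines the division-count
    checkpoints: the counts cannot be measured directly, so they are read off
    simulations run at the experimentally determined cycling speeds.
    """
    geometry = load_fixtures().geometry
    profile = reference_experimental_profile()
    hours = (30.0, 54.0, 102.0)
    acc = {t: [] for t in hours}
    for k in range(replicates):
        cfg = SimulationConfig(seed=(seed * 9176 + k) & 0x7FFFFFFF)
        res = run_mutation_accumulation(cfg, geometry, profile, n_exits=4000)
        for t in hours:
            acc[t].append(res.clock_at(t))
    return {t: int(round(float(np.mean(v)))) for t, v in acc.items()}


def fitting_geometry(stage: str = "L4+1") -> MZGeometry:
    """Lattice covering the DMMZ+MMZ fitting region of the given stage
    (rows distal of the pre-meiotic region), with the cone-like widths."""
    fx = load_fixtures()
    last = fx.compartments[stage]["MMZ"][1]
    widths = fx.geometry.row_capacities[0][:last]
    return MZGeometry((0.0,), (tuple(widths),))


def default_truth_profile(stage: str = "L4+1", ratio: float = 1.5,
                          proximal_h: float = 2.8) -> CellCycleProfile:
    """Ground-truth gradient for synthetic pulse-chase data: two control
    points at the distal end and the proximal end of the MMZ, with the given
    distal/proximal cycle-length ratio (default 1.5: distal stem cells cycle
    1.5x slower)."""
    last = load_fixtures().compartments[stage]["MMZ"][1]
    return CellCycleProfile(
        control_rows=(1, last),
        anchors=(0.0,),
        lengths=((proximal_h * ratio, proximal_h),),
        min_cycle_length=min(2.8, proximal_h),
        phase_fractions=((1, last, DEFAULT_PHASE_FRACTIONS),),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic pulse-chase dataset with known ground truth."""

    profile: CellCycleProfile
    geometry: MZGeometry
    arms_per_chase: int = 20
    chase_times_h: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 5.0, 6.0, 8.0)
    noise_cv: float = 0.10
    edu_misclassification: float = 0.02
    arm_speed_cv: float = 0.05  # biological arm-to-arm cycling-speed spread
    intensity_scale: float = 1000.0  # arbitrary raw-intensity units
    pre_run_h: float = 2.0
    seed: int = 0
    stage: str = "L4+1"

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.arm_speed_cv < 0:
            raise ValueError("noise CVs must be >= 0")
        if not 0.0 <= self.edu_misclassification < 0.5:
            raise ValueError("EdU misclassification must lie in [0, 0.5)")

    @classmethod
    def default(cls, seed: int = 0, **kw) -> "SyntheticSpec":
        stage = kw.pop("stage", "L4+1")
        return cls(
            profile=kw.pop("profile", default_truth_profile(stage)),
            geometry=kw.pop("geometry", fitting_geometry(stage)),
            seed=seed,
            stage=stage,
            **kw,
        )


def generate_pulse_chase(spec: SyntheticSpec):
    """Simulate one arm per (chase time, replicate) and add measurement noise.

    DNA content is perturbed multiplicatively (lognormal, unit mean, CV =
    ``noise_cv``) and scaled to arbitrary intensity units; noisy intensities
    are then renormalized per arm so the 10 % / 85 % quantiles map back to
    2C / 4C.  EdU flags flip with the misclassification rate.  With zero
    noise the records pass through unchanged (already in C units).

    Arms additionally differ biologically: each arm's cycle lengths are
    scaled by a lognormal factor with CV ``arm_speed_cv`` (worm-to-worm
    staging and growth spread), which is what gives the stratified arm
    bootstrap its between-arm variance.  The spatial ratio is unaffected.

    Returns ``(dataset, truth)`` where dataset is a
    :class:`~gonadsim.cellcycle_fitting.PulseChaseDataset` and truth records
    the generating profile and per-cell true values.
    """
    from .cellcycle_fitting import PulseChaseDataset, normalize_dna

    rng = np.random.default_rng(spec.seed)
    frames = []
    arm = 0
    sig_arm = float(np.sqrt(np.log1p(spec.arm_speed_cv**2)))
    for tc in spec.chase_times_h:
        for _ in range(spec.arms_per_chase):
            cfg = SimulationConfig(
                seed=int(rng.integers(0, 2**31 - 1)),
                pre_run_h=spec.pre_run_h,
                chase_times_h=(float(tc),),
            )
            prof = spec.profile
            if spec.arm_speed_cv > 0:
                f = float(rng.lognormal(-0.5 * sig_arm**2, sig_arm))
                prof = CellCycleProfile(
                    control_rows=prof.control_rows,
                    anchors=prof.anchors,
                    lengths=tuple(tuple(v * f for v in row) for row in prof.lengths),
                    min_cycle_length=prof.min_cycle_length * f,
                    phase_fractions=prof.phase_fractions,
                )
            rec = run_pulse_chase(cfg, spec.geometry, prof, arm_id=arm)
            arm += 1
            frames.append(rec)
    records = pd.concat(frames, ignore_index=True)
    records["dna_true"] = records["dna_c"]
    records["edu_true"] = records["edu"]

    if spec.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(records))
        raw = records["dna_true"].to_numpy() * noise * spec.intensity_scale
        dna = np.empty_like(raw)
        for a, idx in records.groupby("arm_id").indices.items():
            dna[idx] = normalize_dna(raw[idx])
        # rare extreme noise draws can renormalize below zero; clamp to a
        # small positive measurement floor (they land in the lowest DNA bin)
        records["dna_c"] = np.maximum(dna, 0.05)
    if spec.edu_misclassification > 0:
        flips = rng.random(len(records)) < spec.edu_misclassification
        records["edu"] = np.where(flips, 1 - records["edu_true"], records["edu_true"])

    compartments = load_fixtures().compartments[spec.stage]
    dataset = PulseChaseDataset(records=records, compartments=dict(compartments))
    truth = {
        "profile": spec.profile,
        "ratio": spec.profile.lengths[0][0] / spec.profile.lengths[0][-1],
        "noise_cv": spec.noise_cv,
        "edu_misclassification": spec.edu_misclassification,
    }
    return dataset, truth


def generate_toy_tree_scenarios() -> dict:
    """Toy pedigree scenarios with enumeration-oracle expectations attached.

    * ``balanced``: a perfectly balanced binary tree of n = 8 cells, the
      pedigree-depth optimum: every cell at depth log2(8) = 3.
    * ``asymmetric_chain``: n = 8 cells produced by 7 successive asymmetric
      divisions of one progenitor; depths {1,...,6,7,7}, mean 4.375.
    * ``tubular_organ``: the single-axis model organ with a stem cell at the
      distal end and differentiation past a threshold of 3 rows; the
      interesting comparison is across alpha (the non-stem/stem cycling-speed
      ratio), where an intermediate alpha minimizes mean pedigree depth and
      the optimal alpha grows with the number of cells produced.
    """
    chain_depths = list(range(1, 8)) + [7]
    return {
        "balanced": {
            "n": 8,
            "depths": [3] * 8,
            "expected_mean_depth": 3.0,
        },
        "asymmetric_chain": {
            "n": 8,
            "depths": chain_depths,
            "expected_mean_depth": float(np.mean(chain_depths)),  # 4.375
        },
        "tubular_organ": {
            "differentiation_row": 3,
            "alphas": (1.0, 1.3, 2.0, 3.0),
            "n_values": (8, 30, 100),
        },
    }
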