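"""Fractional promoter occupancy versus buffered metal concentration.

For each sensor the four coupled equilibria

    P + M  <=> P.M        (K1 = 1/metal Kd)
    P + D  <=> P.D        (K3 = 1/apo DNA Kd)
    P.M + D <=> (P.M).D   (K4 = 1/holo DNA Kd)
    M + B  <=> M.B        (K5, sets the buffered free metal)

are solved simultaneously under mass balances on P (sensor assemblies), D
(operator–promoter copies), M (total metal) and B (buffer).  Metal binding
to the P.D state (the K2 edge of the thermodynamic cycle) is not an
independent parameter — cycle closure fixes K2 = K1*K4/K3 — so the network
is built from the four constants above only.

Occupancy is (P.D + (P.M).D)/D_total for repressor-type sensors; for an
activator only the metalated complex (P.M).D/D_total is the active species.
Curves over a buffered-metal grid are normalised to [0, 1], half-response
set points extracted, and sensors ranked by set point to give the predicted
order of response and the specificity margins between them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import buffer_model
from .buffer_model import DEFAULT_BUFFER_TOTAL, DEFAULT_METAL_TOTAL
from .sensor_params import (
    AffinityConstant,
    CellContext,
    SensorParams,
    average_affinity,
    copies_to_concentration,
    estimate_missing_holo_dna_kd,
)
from .speciation import Reaction, ReactionNetwork, solve_network

__all__ = [
    "OccupancyCurve",
    "SetPointResult",
    "SetPointUndefinedError",
    "modelling_holo_dna_kd",
    "promoter_occupancy",
    "response_curve",
    "normalise_curve",
    "normalise_joint",
    "set_point",
    "rank_sensors",
    "default_grid",
]

default_grid = buffer_model.default_grid

TIE_FOLD = 2.0  # set points closer than this are flagged as overlapping


class SetPointUndefinedError(ValueError):
    """Raised when a normalised curve does not cross 0.5 exactly once."""


@dataclass
class OccupancyCurve:
    sensor: str
    metal: str
    grid: np.ndarray  # buffered metal, molar, strictly increasing
    occupancy: np.ndarray  # raw fractions in [0, 1]
    normalised: np.ndarray | None = None
    response_species: str = "total_bound"  # or "metalated_bound"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.grid.size and np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.occupancy.size and (
            np.any(self.occupancy < -1e-12) or np.any(self.occupancy > 1 + 1e-12)
        ):
            raise ValueError("occupancy values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        data = {"buffered_metal_M": self.grid, "occupancy": self.occupancy}
        if self.normalised is not None:
            data["normalised"] = self.normalised
        return pd.DataFrame(data)


@dataclass
class SetPointResult:
    sensor: str
    metal: str
    set_point: float  # molar
    direction: str  # "rising" | "falling"


@dataclass
class SensorRanking:
    order: list[SetPointResult]
    margins: list[float] = field(default_factory=list)  # fold-ratios between neighbours
    overlapping: list[tuple[str, str]] = field(default_factory=list)


def modelling_holo_dna_kd(
    sensor: SensorParams, metal: str, *, zntr_use_printed_average: bool = False
) -> float:
    """Effective holo-DNA Kd (1/K4) used in the occupancy model.

    Applies the parameter-combination rules: where a sensor's Co and Zn
    holo-DNA affinities agree within error (Zur, RcnR) the arithmetic mean
    of the two drives both metals' models; FrmR's undetermined Co value is
    estimated from its Zn value scaled by the FrmR_E64H Co/Zn
    fold-difference; ZntR defaults to its per-metal values (the printed
    combined average is available via ``zntr_use_printed_average``).
    """
    name = sensor.name
    if name in ("Zur", "RcnR"):
        return average_affinity([a.kd for a in sensor.holo_dna_kd.values()])
    if name == "ZntR" and zntr_use_printed_average:
        printed = sensor.notes.get("averaged_holo_dna_kd_M")
        if printed is None:
            raise KeyError("ZntR registry entry lacks 'averaged_holo_dna_kd_M' note")
        return float(printed)
    if name == "FrmR" and metal not in sensor.holo_dna_kd:
        if metal != "Co" or "Zn" not in sensor.holo_dna_kd:
            raise KeyError(f"sensor {name!r} has no holo DNA Kd for metal {metal!r}")
        # estimate via the E64H variant's Co/Zn fold-difference (2.3e-6/3.5e-6)
        return estimate_missing_holo_dna_kd(
            sensor.holo_dna_kd["Zn"].kd, 2.3e-6, 3.5e-6
        )
    if metal not in sensor.holo_dna_kd:
        raise KeyError(f"sensor {name!r} has no holo DNA Kd for metal {metal!r}")
    return sensor.holo_dna_kd[metal].kd


def _occupancy_network(
    sensor: SensorParams,
    metal: str,
    buffered_metal: float,
    cell: CellContext,
    metal_total: float,
    buffer_total: float,
    holo_dna_kd: float,
) -> ReactionNetwork:
    if metal not in sensor.metal_kd:
        raise KeyError(f"sensor {sensor.name!r} has no metal Kd for {metal!r}")
    k1 = sensor.metal_kd[metal].k_assoc
    k3 = sensor.apo_dna_kd.k_assoc
    k4 = 1.0 / holo_dna_kd
    k5 = buffer_model.k5_for_target(buffered_metal, metal_total, buffer_total)
    return ReactionNetwork(
        reactions=[
            Reaction(("P", "M"), "PM", k1),
            Reaction(("P", "D"), "PD", k3),
            Reaction(("PM", "D"), "PMD", k4),
            Reaction(("M", "B"), "MB", k5),
        ],
        totals={
            "P": copies_to_concentration(sensor.abundance, cell),
            "D": copies_to_concentration(sensor.dna_targets, cell),
            "M": metal_total,
            "B": buffer_total,
        },
    )


def promoter_occupancy(
    sensor: SensorParams,
    buffered_metal: float,
    cell: CellContext = CellContext(),
    metal: str | None = None,
    *,
    metal_total: float = DEFAULT_METAL_TOTAL,
    buffer_total: float = DEFAULT_BUFFER_TOTAL,
    holo_dna_kd: float | None = None,
    zntr_use_printed_average: bool = False,
) -> float:
    """Fractional operator–promoter occupancy at one buffered metal concentration.

    Solves the full four-equilibrium network.  Returns
    ``(PD + PMD)/D_total`` for co-/de-repressors and ``PMD/D_total`` for an
    activator, whose active species is the metalated sensor–DNA complex.
    """
    if buffered_metal < 0:
        raise ValueError("buffered metal concentration must be >= 0")
    if metal is None:
        if len(sensor.metal_kd) != 1:
            raise ValueError(f"sensor {sensor.name!r} senses several metals; pass metal=")
        metal = next(iter(sensor.metal_kd))
    if sensor.abundance == 0:
        return 0.0
    if holo_dna_kd is None:
        holo_dna_kd = modelling_holo_dna_kd(
            sensor, metal, zntr_use_printed_average=zntr_use_printed_average
        )
    if buffered_metal == 0.0:
        # apo limit: two-component P/D competition
        net = ReactionNetwork(
            reactions=[Reaction(("P", "D"), "PD", sensor.apo_dna_kd.k_assoc)],
            totals={
                "P": copies_to_concentration(sensor.abundance, cell),
                "D": copies_to_concentration(sensor.dna_targets, cell),
            },
        )
        state = solve_network(net)
        if sensor.mode == "activator":
            return 0.0
        return state["PD"] / net.totals["D"]
    net = _occupancy_network(
        sensor, metal, buffered_metal, cell, metal_total, buffer_total, holo_dna_kd
    )
    state = solve_network(net)
    d_total = net.totals["D"]
    if sensor.mode == "activator":
        return state["PMD"] / d_total
    return (state["PD"] + state["PMD"]) / d_total


def response_curve(
    sensor: SensorParams,
    metal: str,
    grid=None,
    cell: CellContext = CellContext(),
    *,
    metal_total: float = DEFAULT_METAL_TOTAL,
    buffer_total: float = DEFAULT_BUFFER_TOTAL,
    zntr_use_printed_average: bool = False,
) -> OccupancyCurve:
    """Occupancy over a buffered-metal grid (default 61 log points, 1e-16–1e-3 M)."""
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    holo = modelling_holo_dna_kd(
        sensor, metal, zntr_use_printed_average=zntr_use_printed_average
    )
    occ = np.array(
        [
            promoter_occupancy(
                sensor,
                m,
                cell,
                metal,
                metal_total=metal_total,
                buffer_total=buffer_total,
                holo_dna_kd=holo,
            )
            for m in grid
        ]
    )
    species = "metalated_bound" if sensor.mode == "activator" else "total_bound"
    return OccupancyCurve(sensor.name, metal, grid, occ, response_species=species)


def normalise_curve(curve: OccupancyCurve) -> OccupancyCurve:
    """Affine rescaling of the raw occupancy to span exactly [0, 1]."""
    if curve.occupancy.size == 0:
        raise ValueError("cannot normalise an empty curve")
    lo, hi = float(np.min(curve.occupancy)), float(np.max(curve.occupancy))
    if hi - lo <= 0.0:
        raise ValueError(
            f"curve for {curve.sensor}/{curve.metal} is constant; normalisation undefined"
        )
    return OccupancyCurve(
        curve.sensor,
        curve.metal,
        curve.grid,
        curve.occupancy,
        normalised=(curve.occupancy - lo) / (hi - lo),
        response_species=curve.response_species,
    )


def normalise_joint(curves: list[OccupancyCurve]) -> list[OccupancyCurve]:
    """Normalise several curves by their joint min/max (shared scale).

    Used to keep relative amplitudes visible, e.g. a weaker-binding variant
    whose occupancy never reaches that of the wild type.
    """
    if not curves:
        raise ValueError("no curves to normalise")
    lo = min(float(np.min(c.occupancy)) for c in curves)
    hi = max(float(np.max(c.occupancy)) for c in curves)
    if hi - lo <= 0.0:
        raise ValueError("joint normalisation undefined: all curves constant")
    return [
        OccupancyCurve(
            c.sensor,
            c.metal,
            c.grid,
            c.occupancy,
            normalised=(c.occupancy - lo) / (hi - lo),
            response_species=c.response_species,
        )
        for c in curves
    ]


def set_point(curve: OccupancyCurve) -> SetPointResult:
    """Buffered metal concentration at half-maximal normalised response.

    The 0.5 crossing is interpolated linearly in log10 concentration.  A
    curve that never crosses 0.5, or crosses more than once, has no
    defined set point.
    """
    c = curve if curve.normalised is not None else normalise_curve(curve)
    y = np.asarray(c.normalised) - 0.5
    sign = np.sign(y)
    # treat exact zeros as crossings at the node
    crossings = []
    for i in range(len(y) - 1):
        if sign[i] == 0.0:
            crossings.append((i, float(c.grid[i])))
        elif sign[i] * sign[i + 1] < 0:
            lx0, lx1 = math.log10(c.grid[i]), math.log10(c.grid[i + 1])
            frac = y[i] / (y[i] - y[i + 1])
            crossings.append((i, 10 ** (lx0 + frac * (lx1 - lx0))))
    if sign[-1] == 0.0:
        crossings.append((len(y) - 1, float(c.grid[-1])))
    if len(crossings) != 1:
        raise SetPointUndefinedError(
            f"curve for {curve.sensor}/{curve.metal} crosses 0.5 "
            f"{len(crossings)} times; set point undefined"
        )
    idx, xc = crossings[0]
    direction = "rising" if y[min(idx + 1, len(y) - 1)] > y[idx] else "falling"
    return SetPointResult(curve.sensor, curve.metal, xc, direction)


def rank_sensors(curves: list[OccupancyCurve]) -> SensorRanking:
    """Sort sensors by ascending set point; report margins and near-ties.

    All curves must share the same metal and grid.  Margins are the
    fold-ratios between consecutive set points; pairs closer than
    ``TIE_FOLD`` apart are flagged as overlapping (their predicted order is
    not resolvable).
    """
    if not curves:
        raise ValueError("no curves to rank")
    metals = {c.metal for c in curves}
    if len(metals) != 1:
        raise ValueError(f"cannot rank curves for mixed metals {sorted(metals)}")
    for c in curves[1:]:
        if c.grid.shape != curves[0].grid.shape or not np.allclose(c.grid, curves[0].grid):
            raise ValueError("all curves must share the same buffered-metal grid")
    sps = sorted((set_point(c) for c in curves), key=lambda s: s.set_point)
    margins = [
        sps[i + 1].set_point / sps[i].set_point for i in range(len(sps) - 1)
    ]
    overlapping = [
        (sps[i].sensor, sps[i + 1].sensor)
        for i, m in enumerate(margins)
        if m < TIE_FOLD
    ]
    return SensorRanking(order=sps, margins=margins, overlapping=overlapping)
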