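"""The hypothetical intracellular metal buffer.

A single buffering ligand B holds total metal M at a defined free
("buffered") concentration via ``M + B <=> MB`` with association constant
K5.  Totals default to 0.01 M metal and 0.1 M buffer — metal far above
total sensor protein, buffer tenfold above metal — so the free metal
concentration is set by K5 alone and is essentially untouched by sensor
binding.  Sweeping K5 maps out buffered concentrations from 1e-3 down to
1e-16 M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .speciation import solve_two_component

__all__ = [
    "BufferSpec",
    "DEFAULT_METAL_TOTAL",
    "DEFAULT_BUFFER_TOTAL",
    "buffered_free_metal",
    "k5_for_target",
    "sweep",
    "script_keq_to_per_molar",
]

DEFAULT_METAL_TOTAL = 0.01  # M
DEFAULT_BUFFER_TOTAL = 0.1  # M


@dataclass(frozen=True)
class BufferSpec:
    """Totals and buffer affinity defining one buffered-metal condition."""

    metal_total: float = DEFAULT_METAL_TOTAL
    buffer_total: float = DEFAULT_BUFFER_TOTAL
    k5: float = 0.0  # association constant, per molar

    def __post_init__(self) -> None:
        if self.metal_total < 0 or self.buffer_total < 0 or self.k5 < 0:
            raise ValueError("metal_total, buffer_total and k5 must all be >= 0")
        if self.buffer_total < 10.0 * self.metal_total:
            raise ValueError(
                "buffer_total must be at least tenfold above metal_total "
                f"(got {self.buffer_total} vs {self.metal_total})"
            )


def buffered_free_metal(spec: BufferSpec) -> float:
    """Equilibrium free metal (molar) of ``M + B <=> MB`` for the given spec."""
    state = solve_two_component(spec.k5, spec.metal_total, spec.buffer_total)
    return state["A"]


def script_keq_to_per_molar(script_keq: float) -> float:
    """Convert a legacy modelling-script Keq5 to a per-molar association constant.

    The published worked example pairs Keq5 = 1e-1 with a buffered metal
    concentration of 5.12e-3 M at totals 0.01/0.1 M, which requires an
    association constant of 10 per molar — i.e. the script's equilibrium
    constants are on a 100x molar basis.
    """
    return script_keq * 100.0


def k5_for_target(
    target_free_metal: float,
    metal_total: float = DEFAULT_METAL_TOTAL,
    buffer_total: float = DEFAULT_BUFFER_TOTAL,
) -> float:
    """Closed-form K5 that realises a target buffered free-metal concentration.

    From the mass balances, with m the free metal: MB = M_tot - m and
    B_free = B_tot - M_tot + m, so
    ``K5 = (M_tot - m) / (m * (B_tot - M_tot + m))``.
    """
    if not (0.0 < target_free_metal < metal_total):
        raise ValueError(
            f"target free metal must lie strictly within (0, metal_total); "
            f"got {target_free_metal} with metal_total {metal_total}"
        )
    m = target_free_metal
    return (metal_total - m) / (m * (buffer_total - metal_total + m))


def default_grid(n: int = 61, low: float = 1e-16, high: float = 1e-3) -> np.ndarray:
    """Log-spaced buffered-metal grid, ascending (default 61 points, 1e-16–1e-3 M)."""
    return np.geomspace(low, high, n)


def sweep(
    targets=None,
    metal_total: float = DEFAULT_METAL_TOTAL,
    buffer_total: float = DEFAULT_BUFFER_TOTAL,
) -> list[tuple[float, float]]:
    """Realise each target buffered concentration: (k5, realised free metal) pairs.

    With no targets given, the default grid spans 1e-16–1e-3 M (fourteen
    decades, ascending, one point per grid node).
    """
    if targets is None:
        targets = default_grid()
    out = []
    for t in np.asarray(targets, dtype=float):
        k5 = k5_for_target(t, metal_total, buffer_total)
        realised = buffered_free_metal(BufferSpec(metal_total, buffer_total, k5))
        out.append((k5, realised))
    return out
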