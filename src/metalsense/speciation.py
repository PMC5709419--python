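"""Exact solution of coupled binding-equilibrium networks.

A network is a set of bimolecular association reactions ``A + B <=> AB``
with association constants ``K`` (per molar), plus total concentrations for
the *base* species (those that are never the product of a reaction).  Every
complex concentration follows from the free base concentrations by mass
action; the solver finds the free concentrations that satisfy every mass
balance.

Two entry points:

* :func:`solve_two_component` — the single-reaction case, solved in closed
  form via the ligand-depletion quadratic.
* :func:`solve_network` — the general case, solved by a damped Newton
  iteration in log free-concentration space with a per-coordinate bisection
  fallback.  Free concentrations in these systems span ~1e-16–1e-1 M, so
  iterating in log space keeps the Jacobian well conditioned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "SpeciationState",
    "NetworkValidationError",
    "SolverError",
    "solve_two_component",
    "solve_network",
]

DEFAULT_TOLERANCE = 1e-10
_MAX_NEWTON_ITER = 200


class NetworkValidationError(ValueError):
    """Raised when a reaction network is structurally invalid."""


class SolverError(RuntimeError):
    """Raised when the equilibrium solver fails to converge."""


@dataclass(frozen=True)
class Reaction:
    """One bimolecular association ``reactants[0] + reactants[1] <=> product``."""

    reactants: tuple[str, str]
    product: str
    k_assoc: float  # per molar

    def __post_init__(self) -> None:
        if len(self.reactants) != 2:
            raise NetworkValidationError(
                f"reaction forming {self.product!r} must have exactly two reactants"
            )
        if not (self.k_assoc >= 0.0) or math.isinf(self.k_assoc):
            raise NetworkValidationError(
                f"association constant for {self.product!r} must be finite and >= 0"
            )
        if self.product in self.reactants:
            raise NetworkValidationError(
                f"product {self.product!r} cannot be one of its own reactants"
            )


@dataclass
class ReactionNetwork:
    """Reactions plus totals for base species (molar)."""

    reactions: list[Reaction]
    totals: dict[str, float]

    def __post_init__(self) -> None:
        products = [r.product for r in self.reactions]
        if len(set(products)) != len(products):
            raise NetworkValidationError("each species may be the product of at most one reaction")
        for name, tot in self.totals.items():
            if not (tot >= 0.0):
                raise NetworkValidationError(f"total for {name!r} must be >= 0")
            if name in products:
                raise NetworkValidationError(
                    f"{name!r} is a reaction product and cannot carry a total"
                )
        known = set(self.totals)
        remaining = list(self.reactions)
        # topological check: every reactant is a base species or an earlier product
        while remaining:
            progress = [r for r in remaining if all(s in known for s in r.reactants)]
            if not progress:
                bad = sorted({s for r in remaining for s in r.reactants} - known)
                raise NetworkValidationError(
                    f"species {bad} are neither base species with totals nor products "
                    "of other reactions (or the product graph is cyclic)"
                )
            for r in progress:
                known.add(r.product)
            remaining = [r for r in remaining if r not in progress]

    @property
    def base_species(self) -> list[str]:
        return list(self.totals)

    @property
    def product_species(self) -> list[str]:
        return [r.product for r in self.reactions]

    def ordered_reactions(self) -> list[Reaction]:
        """Reactions sorted so every reactant precedes its product."""
        known = set(self.totals)
        ordered: list[Reaction] = []
        remaining = list(self.reactions)
        while remaining:
            batch = [r for r in remaining if all(s in known for s in r.reactants)]
            for r in batch:
                known.add(r.product)
                ordered.append(r)
            remaining = [r for r in remaining if r not in batch]
        return ordered

    def stoichiometry(self) -> dict[str, dict[str, int]]:
        """Map species -> {base species: count} composition."""
        comp: dict[str, dict[str, int]] = {b: {b: 1} for b in self.totals}
        for r in self.ordered_reactions():
            merged: dict[str, int] = {}
            for s in r.reactants:
                for b, n in comp[s].items():
                    merged[b] = merged.get(b, 0) + n
            comp[r.product] = merged
        return comp


@dataclass
class SpeciationState:
    """Solved equilibrium concentrations and mass-balance residuals."""

    concentrations: dict[str, float]
    residuals: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, species: str) -> float:
        return self.concentrations[species]


def solve_two_component(k_assoc: float, total_a: float, total_b: float) -> SpeciationState:
    """Solve ``A + B <=> AB`` exactly via the depletion quadratic.

    Each free concentration is computed from its own quadratic in the
    cancellation-free form; e.g. free A solves
    ``K*a^2 + (K*(B0 - A0) + 1)*a - A0 = 0``, evaluated as
    ``a = 2*A0 / (q_a + sqrt(q_a^2 + 4*K*A0))`` with
    ``q_a = K*(B0 - A0) + 1``.  This stays accurate even when binding is so
    tight that the free concentration is many orders of magnitude below the
    total (where ``total - complex`` would lose all precision).

    Parameters
    ----------
    k_assoc : association constant, per molar.
    total_a, total_b : total concentrations, molar.
    """
    if not (k_assoc >= 0.0):
        raise ValueError("k_assoc must be >= 0")
    if not (total_a >= 0.0 and total_b >= 0.0):
        raise ValueError("totals must be >= 0")
    if k_assoc == 0.0 or total_a == 0.0 or total_b == 0.0:
        free_a, free_b, ab = total_a, total_b, 0.0
    else:
        def stable_root(total_self: float, total_other: float, k: float) -> float:
            # positive root of k*x^2 + q*x - total_self = 0, picking the
            # algebraic form that adds same-signed terms
            q = k * (total_other - total_self) + 1.0
            disc = math.sqrt(q * q + 4.0 * k * total_self)
            if q >= 0.0:
                return 2.0 * total_self / (q + disc)
            return (disc - q) / (2.0 * k)

        free_a = stable_root(total_a, total_b, k_assoc)
        free_b = stable_root(total_b, total_a, k_assoc)
        ab = k_assoc * free_a * free_b
    res_a = abs(free_a + ab - total_a) / total_a if total_a > 0 else 0.0
    res_b = abs(free_b + ab - total_b) / total_b if total_b > 0 else 0.0
    return SpeciationState(
        concentrations={"A": free_a, "B": free_b, "AB": ab},
        residuals={"A": res_a, "B": res_b},
    )


def _species_concentrations(
    net: ReactionNetwork, free: dict[str, float]
) -> dict[str, float]:
    conc = dict(free)
    for r in net.ordered_reactions():
        conc[r.product] = r.k_assoc * conc[r.reactants[0]] * conc[r.reactants[1]]
    return conc


def _totals_from_free(
    net: ReactionNetwork,
    comp: dict[str, dict[str, int]],
    free: dict[str, float],
) -> dict[str, float]:
    conc = _species_concentrations(net, free)
    implied = {b: free[b] for b in net.totals}
    for r in net.reactions:
        for b, n in comp[r.product].items():
            implied[b] += n * conc[r.product]
    return implied


def solve_network(
    net: ReactionNetwork, tolerance: float = DEFAULT_TOLERANCE
) -> SpeciationState:
    """Solve a validated network to the requested relative mass-balance error.

    Works in log free-concentration space of the base species with nonzero
    totals.  A damped Newton step on ``log(implied_total) - log(total)`` is
    tried first; any coordinate the Newton step fails to improve falls back
    to bisection on its own (monotone) mass-balance equation.  Deterministic
    for fixed inputs.
    """
    if not (tolerance > 0.0):
        raise ValueError("tolerance must be > 0")
    comp = net.stoichiometry()

    active = [b for b in net.totals if net.totals[b] > 0.0]
    zero = [b for b in net.totals if net.totals[b] == 0.0]

    if not active:
        conc = {b: 0.0 for b in net.totals}
        for r in net.reactions:
            conc[r.product] = 0.0
        return SpeciationState(conc, {b: 0.0 for b in net.totals})

    # any complex containing a zero-total base species is identically zero,
    # so solve the reduced network over the active species only
    def implied_totals(log_free: np.ndarray) -> np.ndarray:
        free = {b: 0.0 for b in zero}
        free.update({b: math.exp(x) for b, x in zip(active, log_free)})
        implied = _totals_from_free(net, comp, free)
        return np.array([implied[b] for b in active])

    totals = np.array([net.totals[b] for b in active])
    x = np.log(totals)  # initial guess: free = total

    def residual(xv: np.ndarray) -> np.ndarray:
        return np.log(implied_totals(xv)) - np.log(totals)

    f = residual(x)
    for _ in range(_MAX_NEWTON_ITER):
        if np.max(np.abs(np.expm1(f))) < tolerance:
            break
        # finite-difference Jacobian in log space (networks here are tiny)
        n = len(x)
        jac = np.empty((n, n))
        h = 1e-7
        for j in range(n):
            xp = x.copy()
            xp[j] += h
            jac[:, j] = (residual(xp) - f) / h
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError:
            step = -f
        step = np.clip(step, -5.0, 5.0)
        # damped line search on the max log-residual
        best_norm = np.max(np.abs(f))
        lam = 1.0
        improved = False
        for _ in range(30):
            x_try = x + lam * step
            f_try = residual(x_try)
            if np.max(np.abs(f_try)) < best_norm:
                x, f = x_try, f_try
                improved = True
                break
            lam *= 0.5
        if not improved:
            # coordinate-wise bisection fallback: each mass balance is
            # monotone increasing in its own log free concentration
            for i in range(n):
                lo, hi = x[i] - 60.0, math.log(totals[i]) + 1e-12
                for _ in range(200):
                    mid = 0.5 * (lo + hi)
                    x[i] = mid
                    if residual(x)[i] > 0.0:
                        hi = mid
                    else:
                        lo = mid
                x[i] = 0.5 * (lo + hi)
            f = residual(x)
    else:
        if np.max(np.abs(np.expm1(f))) >= tolerance:
            raise SolverError(
                "equilibrium solver did not converge: residuals "
                f"{dict(zip(active, np.expm1(f)))}, totals {net.totals}, "
                f"reactions {[(r.reactants, r.product, r.k_assoc) for r in net.reactions]}"
            )

    free = {b: 0.0 for b in zero}
    free.update({b: math.exp(v) for b, v in zip(active, x)})
    conc = _species_concentrations(net, free)
    implied = _totals_from_free(net, comp, free)
    residuals = {
        b: (abs(implied[b] - net.totals[b]) / net.totals[b] if net.totals[b] > 0 else 0.0)
        for b in net.totals
    }
    return SpeciationState(conc, residuals)
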