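"""Equilibrium solver: closed form, network solver, and a grid-search oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from metalsense.speciation import (
    NetworkValidationError,
    Reaction,
    ReactionNetwork,
    solve_network,
    solve_two_component,
)


def bisection_free_a(k, a0, b0):
    """Independent scalar oracle for A + B <=> AB on the A mass balance."""
    if k == 0 or a0 == 0 or b0 == 0:
        return a0

    def f(a):
        return a * (1 + k * b0 / (1 + k * a)) - a0

    return brentq(f, 0.0, a0, xtol=1e-320, rtol=1e-15)


def grid_oracle(net, rounds=14, pts=15):
    """Dense log-grid search over free base concentrations, with refinement.

    Minimises the worst relative mass-balance error; independent of the
    Newton path used by solve_network.
    """
    bases = [b for b in net.totals if net.totals[b] > 0]
    comp = net.stoichiometry()
    ordered = net.ordered_reactions()
    lo = np.array([np.log10(net.totals[b]) - 18.0 for b in bases])
    hi = np.array([np.log10(net.totals[b]) for b in bases])
    best = None
    for _ in range(rounds):
        axes = [np.linspace(lo[i], hi[i], pts) for i in range(len(bases))]
        mesh = np.meshgrid(*axes, indexing="ij")
        free = {b: 10.0 ** mesh[i] for i, b in enumerate(bases)}
        conc = dict(free)
        for r in ordered:
            conc[r.product] = r.k_assoc * conc[r.reactants[0]] * conc[r.reactants[1]]
        err = np.zeros_like(mesh[0])
        for i, b in enumerate(bases):
            implied = free[b].copy()
            for r in net.reactions:
                implied = implied + comp[r.product].get(b, 0) * conc[r.product]
            err = np.maximum(err, np.abs(implied - net.totals[b]) / net.totals[b])
        idx = np.unravel_index(np.argmin(err), err.shape)
        centre = np.array([axes[i][idx[i]] for i in range(len(bases))])
        span = (hi - lo) / (pts - 1)
        lo, hi = centre - 3 * span, np.minimum(centre + 3 * span, hi)
        best = {b: 10.0 ** centre[i] for i, b in enumerate(bases)}

    # polish by Gauss-Seidel bisection: each base's mass balance is monotone
    # increasing in its own free concentration with the others held fixed
    def implied_total(free, b):
        conc = dict(free)
        for r in ordered:
            conc[r.product] = r.k_assoc * conc[r.reactants[0]] * conc[r.reactants[1]]
        return free[b] + sum(
            comp[r.product].get(b, 0) * conc[r.product] for r in net.reactions
        )

    for _ in range(200):
        worst = 0.0
        for b in bases:
            lo_b, hi_b = 0.0, net.totals[b]
            for _ in range(100):
                mid = 0.5 * (lo_b + hi_b)
                best[b] = mid
                if implied_total(best, b) > net.totals[b]:
                    hi_b = mid
                else:
                    lo_b = mid
            best[b] = 0.5 * (lo_b + hi_b)
            worst = max(
                worst,
                abs(implied_total(best, b) - net.totals[b]) / net.totals[b],
            )
        if worst < 1e-12:
            break
    conc = dict(best)
    for r in ordered:
        conc[r.product] = r.k_assoc * conc[r.reactants[0]] * conc[r.reactants[1]]
    for b in net.totals:
        if net.totals[b] == 0:
            conc[b] = 0.0
            for r in net.reactions:
                if comp[r.product].get(b, 0):
                    conc[r.product] = 0.0
    return conc


class TestTwoComponent:
    def test_buffered_metal_worked_example(self):
        st_ = solve_two_component(10.0, 0.01, 0.1)
        assert st_["A"] == pytest.approx(5.12e-3, rel=1e-3)

    def test_no_binding(self):
        st_ = solve_two_component(0.0, 0.01, 0.1)
        assert st_["A"] == 0.01
        assert st_["AB"] == 0.0

    def test_tight_binding_limit(self):
        # K = 1e9/M, A0 = 1 uM, B0 = 1 mM: nearly all A bound
        st_ = solve_two_component(1e9, 1e-6, 1e-3)
        oracle = bisection_free_a(1e9, 1e-6, 1e-3)
        assert st_["A"] == pytest.approx(oracle, rel=1e-9)
        assert st_["A"] == pytest.approx(1.0e-12, rel=0.01)

    @given(
        logk=st.floats(min_value=0, max_value=15),
        loga=st.floats(min_value=-12, max_value=-1),
        logb=st.floats(min_value=-12, max_value=-1),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_scalar_oracle(self, logk, loga, logb):
        k, a0, b0 = 10.0**logk, 10.0**loga, 10.0**logb
        st_ = solve_two_component(k, a0, b0)
        assert st_["A"] == pytest.approx(bisection_free_a(k, a0, b0), rel=1e-9)

    @given(
        logk=st.floats(min_value=0, max_value=15),
        loga=st.floats(min_value=-12, max_value=-1),
        logb=st.floats(min_value=-12, max_value=-1),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_and_nonnegativity(self, logk, loga, logb):
        k, a0, b0 = 10.0**logk, 10.0**loga, 10.0**logb
        st_ = solve_two_component(k, a0, b0)
        assert st_["A"] >= 0 and st_["B"] >= 0 and st_["AB"] >= 0
        assert st_["A"] + st_["AB"] == pytest.approx(a0, rel=1e-12)
        assert st_["B"] + st_["AB"] == pytest.approx(b0, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_two_component(-1.0, 0.01, 0.1)
        with pytest.raises(ValueError):
            solve_two_component(1.0, -0.01, 0.1)


def fig6_network(k1, k3, k4, k5, p, d, m, b):
    return ReactionNetwork(
        reactions=[
            Reaction(("P", "M"), "PM", k1),
            Reaction(("P", "D"), "PD", k3),
            Reaction(("PM", "D"), "PMD", k4),
            Reaction(("M", "B"), "MB", k5),
        ],
        totals={"P": p, "D": d, "M": m, "B": b},
    )


class TestNetwork:
    def test_all_totals_zero(self):
        net = ReactionNetwork(
            reactions=[Reaction(("A", "B"), "AB", 1e6)], totals={"A": 0.0, "B": 0.0}
        )
        st_ = solve_network(net)
        assert st_["A"] == st_["B"] == st_["AB"] == 0.0

    def test_single_reaction_matches_closed_form(self):
        for k, a0, b0 in [(1e7, 1e-6, 5e-7), (10.0, 0.01, 0.1), (1e12, 1e-9, 1e-8)]:
            net = ReactionNetwork(
                reactions=[Reaction(("A", "B"), "AB", k)], totals={"A": a0, "B": b0}
            )
            st_ = solve_network(net, tolerance=1e-13)
            cf = solve_two_component(k, a0, b0)
            assert st_["A"] == pytest.approx(cf["A"], rel=1e-12)
            assert st_["AB"] == pytest.approx(cf["AB"], rel=1e-12)

    def test_metal_excess_reduces_to_two_component(self):
        # sensor network with M_total >> P_total: free metal is set by the
        # buffer equilibrium alone
        net = fig6_network(
            k1=1e8, k3=1e6, k4=1e7, k5=1e5, p=1e-9, d=6.6e-10, m=0.01, b=0.1
        )
        st_ = solve_network(net)
        cf = solve_two_component(1e5, 0.01, 0.1)
        assert st_["M"] == pytest.approx(cf["A"], rel=1e-6)

    def test_residuals_within_tolerance(self):
        net = fig6_network(
            k1=1 / 5.1e-10, k3=1 / 1.5e-7, k4=1 / 1.4e-5, k5=1e9,
            p=3.65e-8, d=1.66e-9, m=0.01, b=0.1,
        )
        st_ = solve_network(net)
        assert all(r < 1e-10 for r in st_.residuals.values())
        assert all(c >= 0 for c in st_.concentrations.values())

    def test_zero_total_shortcircuits(self):
        net = fig6_network(1e8, 1e6, 1e7, 1e5, p=0.0, d=6.6e-9, m=0.01, b=0.1)
        st_ = solve_network(net)
        assert st_["PD"] == 0.0 and st_["PMD"] == 0.0 and st_["PM"] == 0.0

    def test_monotone_in_association_constant(self):
        base = dict(k1=1e8, k3=1e6, k4=1e7, k5=1e6, p=3.5e-8, d=6.6e-9, m=0.01, b=0.1)
        pd_low = solve_network(fig6_network(**base))["PD"]
        stronger = dict(base, k3=1e7)
        pd_high = solve_network(fig6_network(**stronger))["PD"]
        assert pd_high > pd_low

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_base = int(rng.integers(2, 4))
        bases = [f"S{i}" for i in range(n_base)]
        totals = {b: 10.0 ** rng.uniform(-8, -3) for b in bases}
        reactions = []
        species_pool = list(bases)
        for j in range(int(rng.integers(1, n_base + 1))):
            r1, r2 = rng.choice(species_pool, size=2, replace=True)
            prod = f"C{j}"
            reactions.append(Reaction((str(r1), str(r2)), prod, 10.0 ** rng.uniform(2, 9)))
            species_pool.append(prod)
        net = ReactionNetwork(reactions=reactions, totals=totals)
        st_ = solve_network(net)
        oracle = grid_oracle(net)
        for sp, val in oracle.items():
            ref = max(val, 1e-30)
            assert st_.concentrations[sp] == pytest.approx(val, rel=0.01, abs=1e-12), sp


class TestValidation:
    def test_duplicate_product_rejected(self):
        with pytest.raises(NetworkValidationError):
            ReactionNetwork(
                reactions=[
                    Reaction(("A", "B"), "AB", 1.0),
                    Reaction(("A", "A"), "AB", 1.0),
                ],
                totals={"A": 1e-6, "B": 1e-6},
            )

    def test_orphan_species_rejected(self):
        with pytest.raises(NetworkValidationError):
            ReactionNetwork(
                reactions=[Reaction(("A", "X"), "AX", 1.0)], totals={"A": 1e-6}
            )

    def test_negative_total_rejected(self):
        with pytest.raises(NetworkValidationError):
            ReactionNetwork(
                reactions=[Reaction(("A", "B"), "AB", 1.0)],
                totals={"A": -1e-6, "B": 1e-6},
            )

    def test_negative_k_rejected(self):
        with pytest.raises(NetworkValidationError):
            Reaction(("A", "B"), "AB", -5.0)
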