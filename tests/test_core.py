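import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from crnpde.core import (
    CRN,
    CRNError,
    DualRailSignal,
    Reaction,
    add_dual_rail,
    closed_form_decay,
    dual_rail_encode,
    dual_rail_read,
    mass_action_odes,
    rate_laws,
    simulate,
    steady_state,
    stoichiometry_matrix,
    symbolic_odes,
)


def eq90_system(theta=0.003, k=0.002, gamma=0.01, mu=0.001) -> CRN:
    crn = CRN("eq90")
    crn.add_species("Sa", initial=2.0)
    crn.add_species("Sb", initial=1.0)
    crn.add_species("Sc", initial=0.0)
    crn.add_reaction({"Sa": 1, "Sb": 1}, {"Sc": 1}, theta)
    crn.add_reaction({"Sa": 1}, {"Sa": 1, "Sb": 1}, k)
    crn.add_reaction({"Sb": 1}, {}, gamma)
    crn.add_reaction({"Sc": 1}, {"Sc": 2}, mu)
    return crn


class TestMassActionOdes:
    def test_bimolecular_binding_matches_printed_rate_law(self):
        theta, k, gamma, mu = 0.003, 0.002, 0.01, 0.001
        crn = eq90_system(theta, k, gamma, mu)
        f, order = mass_action_odes(crn)
        y = np.array([2.0, 1.0, 0.5])
        dy = f(0.0, y)
        sa, sb, sc = y
        assert dy[order.index("Sa")] == pytest.approx(-theta * sa * sb)
        assert dy[order.index("Sb")] == pytest.approx(-theta * sa * sb + k * sa - gamma * sb)
        assert dy[order.index("Sc")] == pytest.approx(theta * sa * sb + mu * sc)

    def test_empty_crn_all_zero(self):
        crn = CRN()
        crn.add_species("A", initial=1.0)
        f, _ = mass_action_odes(crn)
        assert np.all(f(0.0, np.array([1.0])) == 0.0)

    def test_catalysis_net_zero_for_catalyst(self):
        crn = CRN()
        crn.add_reaction({"A": 1}, {"A": 1, "B": 1}, 0.5)
        crn.initial["A"] = 2.0
        f, order = mass_action_odes(crn)
        dy = f(0.0, np.array([2.0, 0.0]))
        assert dy[order.index("A")] == 0.0
        assert dy[order.index("B")] == pytest.approx(0.5 * 2.0)

    def test_clamped_species_frozen(self):
        crn = CRN()
        crn.clamp("A", 1.0)
        crn.add_reaction({"A": 1}, {}, 1.0)
        f, order = mass_action_odes(crn)
        assert f(0.0, np.array([1.0]))[order.index("A")] == 0.0

    def test_undeclared_species_rejected(self):
        crn = CRN()
        crn.add_species("A")
        with pytest.raises(CRNError):
            crn.add_reaction({"A": 1, "B": 1}, {}, 1.0, declare=False)

    def test_order_above_three_rejected(self):
        with pytest.raises(CRNError):
            Reaction({"A": 2, "B": 2}, {}, 1.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(CRNError):
            Reaction({"A": 1}, {}, -1.0)


class TestStoichiometryMatrix:
    def test_binding_column(self):
        crn = eq90_system()
        mat = stoichiometry_matrix(crn)
        order = crn.species_order()
        col = mat[:, 0]
        assert col[order.index("Sa")] == -1
        assert col[order.index("Sb")] == -1
        assert col[order.index("Sc")] == 1

    def test_annihilation_column(self):
        crn = CRN()
        crn.add_reaction({"A": 1, "B": 1}, {}, 1.0)
        mat = stoichiometry_matrix(crn)
        assert sorted(mat[:, 0]) == [-1, -1]

    def test_autocatalysis_net_plus_one(self):
        crn = eq90_system()
        mat = stoichiometry_matrix(crn)
        assert mat[crn.species_order().index("Sc"), 3] == 1


_species_pool = ["A", "B", "C", "D", "E", "F"]


@st.composite
def small_crns(draw):
    crn = CRN("random")
    n_species = draw(st.integers(2, 6))
    names = _species_pool[:n_species]
    for n in names:
        crn.add_species(n, initial=draw(st.floats(0.0, 3.0)))
    n_rxn = draw(st.integers(1, 8))
    for _ in range(n_rxn):
        order = draw(st.integers(1, 3))
        reactants = draw(
            st.lists(st.sampled_from(names), min_size=order, max_size=order)
        )
        products = draw(st.lists(st.sampled_from(names), min_size=0, max_size=3))
        rate = draw(st.floats(1e-4, 1e-1))
        crn.add_reaction(reactants, products, rate)
    return crn


class TestOdeStoichConsistency:
    @given(small_crns())
    @settings(max_examples=30, deadline=None)
    def test_symbolic_identity(self, crn):
        # d[s]/dt must equal (stoichiometry matrix @ rate-law vector)[s]
        exprs, syms = symbolic_odes(crn)
        order = crn.species_order()
        mat = stoichiometry_matrix(crn)
        from crnpde.core import _elementary

        v = []
        for rxn in _elementary(crn):
            flux = sympy.Float(rxn.rate)
            for name, m in rxn.reactants.items():
                flux *= syms[name] ** m
            v.append(flux)
        recomposed = mat @ sympy.Matrix(v)
        for i, name in enumerate(order):
            assert sympy.simplify(exprs[name] - recomposed[i]) == 0

    @given(small_crns())
    @settings(max_examples=15, deadline=None)
    def test_nonnegativity(self, crn):
        traj = simulate(crn, 50.0, n_points=60, check_steady=False, rtol=1e-6, atol=1e-9)
        assert traj.states.min() >= -1e-9


class TestSimulate:
    def test_unimolecular_decay_closed_form(self):
        gamma = 0.7
        crn = CRN()
        crn.add_species("A", initial=1.0)
        crn.add_reaction({"A": 1}, {}, gamma)
        traj = simulate(crn, 10.0, n_points=200, check_steady=False)
        expected = closed_form_decay(1.0, gamma, traj.times)
        assert np.max(np.abs(traj["A"] - expected)) < 1e-6

    def test_catalytic_production_reaches_ratio(self):
        k = 0.05
        crn = CRN()
        crn.clamp("A", 1.0)
        crn.add_reaction({"A": 1}, {"A": 1, "B": 1}, k)
        crn.add_reaction({"B": 1}, {}, k)
        traj = simulate(crn, 400.0)
        assert traj.final("B") == pytest.approx(1.0, abs=1e-6)
        assert traj.steady_state_reached

    def test_eq90_bounded_nonnegative(self):
        traj = simulate(eq90_system(), 2000.0, check_steady=False)
        assert traj.states.min() >= 0.0
        assert np.isfinite(traj.states).all()

    def test_t_end_must_be_positive(self):
        with pytest.raises(ValueError):
            simulate(CRN(), 0.0)

    def test_csv_export_roundtrip(self, tmp_path):
        crn = CRN()
        crn.add_species("A", initial=1.0)
        crn.add_reaction({"A": 1}, {}, 0.1)
        traj = simulate(crn, 5.0, n_points=20, check_steady=False)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["time", "A"]
        assert np.allclose(df["A"].to_numpy(), traj["A"])


class TestSteadyState:
    def test_constant_trajectory_converged(self):
        crn = CRN()
        crn.clamp("A", 2.0)
        traj = simulate(crn, 10.0)
        vals, converged = steady_state(traj, ["A"])
        assert converged and vals["A"] == pytest.approx(2.0)

    def test_decayed_exponential_converged_to_zero(self):
        crn = CRN()
        crn.add_species("A", initial=1.0)
        crn.add_reaction({"A": 1}, {}, 1.0)
        traj = simulate(crn, 60.0)
        vals, converged = steady_state(traj, ["A"], rel_tol=1e-6)
        assert converged
        assert vals["A"] == pytest.approx(0.0, abs=1e-9)

    def test_linear_growth_not_converged(self):
        crn = CRN()
        crn.clamp("A", 1.0)
        crn.add_reaction({"A": 1}, {"A": 1, "B": 1}, 1.0)
        traj = simulate(crn, 100.0)
        _, converged = steady_state(traj, ["B"], rel_tol=1e-6)
        assert not converged

    def test_window_longer_than_trajectory_rejected(self):
        crn = CRN()
        crn.clamp("A", 1.0)
        traj = simulate(crn, 10.0)
        with pytest.raises(ValueError):
            steady_state(traj, ["A"], window=20.0)


class TestDualRail:
    def test_encode_positive(self):
        crn = CRN()
        pair = add_dual_rail(crn, "Rp", "Rm", 1e3)
        enc = dual_rail_encode(crn, 1.5, pair)
        assert enc == {"Rp": 1.5, "Rm": 0.0}
        assert dual_rail_read(crn.initial, pair) == pytest.approx(1.5)

    def test_encode_negative(self):
        crn = CRN()
        pair = add_dual_rail(crn, "Rp", "Rm", 1e3)
        enc = dual_rail_encode(crn, -2.0, pair)
        assert enc == {"Rp": 0.0, "Rm": 2.0}
        assert dual_rail_read(crn.initial, pair) == pytest.approx(-2.0)

    def test_read_mixed_state(self):
        pair = DualRailSignal("Rp", "Rm")
        assert dual_rail_read({"Rp": 3.0, "Rm": 1.0}, pair) == pytest.approx(2.0)

    @given(st.floats(-100, 100))
    @settings(max_examples=50)
    def test_encode_read_inverse(self, value):
        crn = CRN()
        pair = add_dual_rail(crn, "Rp", "Rm", 1e3)
        enc = dual_rail_encode(crn, value, pair)
        assert min(enc.values()) == 0.0 or value == 0.0
        assert dual_rail_read(enc, pair) == pytest.approx(value)

    def test_missing_annihilation_warns(self, caplog):
        crn = CRN()
        crn.add_species("Rp")
        crn.add_species("Rm")
        pair = DualRailSignal("Rp", "Rm")
        import logging

        with caplog.at_level(logging.WARNING, logger="crnpde"):
            dual_rail_encode(crn, 1.0, pair)
        assert any("annihilation" in r.message for r in caplog.records)


class TestMergeAndRates:
    def test_duplicate_reactions_sum_rates(self):
        a, b = CRN(), CRN()
        a.add_reaction({"A": 1}, {}, 0.5)
        b.add_reaction({"A": 1}, {}, 0.25)
        a.merge(b)
        assert len(a.reactions) == 1
        assert a.reactions[0].rate == pytest.approx(0.75)

    def test_rate_laws_match_flux(self):
        crn = eq90_system()
        y = np.array([crn.initial[n] for n in crn.species_order()])
        fluxes = rate_laws(crn, y)
        assert fluxes[0] == pytest.approx(0.003 * 2.0 * 1.0)
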