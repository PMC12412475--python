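import logging

import numpy as np
import pytest

from crnpde.core import CRN, Reaction, simulate
from crnpde.dsd import (
    DEFAULT_QMAX,
    DsdProgram,
    InfeasibleRateError,
    UnsupportedReactionError,
    _Namer,
    classify_species,
    compile_crn,
    compile_reaction,
    export_dsd_script,
    parse_dsd_script,
    rate_map_check,
    validate_equivalence,
)


def uni_catalysis_crn(k=1e-3):
    crn = CRN("uni_cat")
    crn.add_species("A", initial=1.0)
    crn.add_species("B")
    crn.add_reaction({"A": 1}, {"A": 1, "B": 1}, k)
    crn.add_reaction({"B": 1}, {}, k)
    return crn


class TestTemplates:
    def test_trimolecular_literal_structure(self):
        # literal printed cascade: 4 steps, first two reversible
        crn = CRN()
        crn.add_reaction({"In": 1, "Wi": 1, "Xi": 1}, {"Xi": 1, "In": 2}, 5e-6)
        prog = compile_crn(crn, buffered=False)
        steps = prog.reactions
        assert len(steps) == 4
        assert steps[0].reversible and steps[1].reversible
        assert not steps[2].reversible and not steps[3].reversible
        # slow step carries q_i = k*Cmax; every other step runs at qmax
        assert steps[0].rate == pytest.approx(5e-6 * prog.cmax)
        assert all(s.rate == prog.qmax for s in steps[1:])
        # final step releases the ideal products
        assert steps[3].products["In"] == 2 and steps[3].products["Xi"] == 1

    def test_trimolecular_literal_classification(self):
        crn = CRN()
        crn.add_reaction({"In": 1, "Wi": 1, "Xi": 1}, {"Xi": 1, "In": 2}, 5e-6)
        prog = compile_crn(crn, buffered=False)
        by_stem = lambda stem, s: any(n.startswith(stem) for n in s)  # noqa: E731
        assert by_stem("Hd", prog.set_as)  # consumed auxiliary
        assert by_stem("Hb", prog.set_is)  # shuttling intermediate
        assert by_stem("Ha", prog.set_iw)  # inert displaced strand
        assert "Waste" in prog.set_iw

    def test_unimolecular_degradation_single_step(self):
        crn = CRN()
        crn.add_species("Dau", initial=1.0)
        crn.add_reaction({"Dau": 1}, {}, 3.0e-3)
        prog = compile_crn(crn)
        assert len(prog.reactions) == 1
        assert prog.reactions[0].rate == pytest.approx(3.0e-3 / 1000.0)  # k/Cmax
        assert not prog.reactions[0].products

    def test_annihilation_two_steps_ending_in_waste(self):
        crn = CRN()
        crn.add_species("Umm", initial=1.0)
        crn.add_species("Unn", initial=1.0)
        crn.add_reaction({"Umm": 1, "Unn": 1}, {}, 1e-3)
        prog = compile_crn(crn)
        assert len(prog.reactions) == 2
        assert prog.reactions[0].rate == pytest.approx(1e-3)  # qi = k for bimolecular
        assert prog.reactions[1].products == {"Waste": 1}

    def test_order_zero_unsupported(self):
        prog = DsdProgram()
        with pytest.raises(UnsupportedReactionError):
            compile_reaction(Reaction({}, {"A": 1}, 1.0), prog, _Namer())

    def test_adjustment_kept_verbatim(self):
        crn = CRN()
        crn.add_reaction({"W": 1, "La": 1}, {"Lb": 1}, 3.65e-6, 9e-5)
        prog = compile_crn(crn)
        assert len(prog.reactions) == 1
        assert prog.reactions[0].rate == pytest.approx(3.65e-6)
        assert prog.reactions[0].reverse_rate == pytest.approx(9e-5)


class TestClassification:
    def test_sets_disjoint_and_cover(self):
        crn = uni_catalysis_crn()
        prog = compile_crn(crn)
        sets = classify_species(prog)
        union = sets["Set_AS"] | sets["Set_IS"] | sets["Set_IW"]
        assert not (union & prog.signals)
        seen = set()
        for r in prog.reactions:
            seen |= r.species_names()
        assert seen - prog.signals <= union

    def test_empty_program(self):
        prog = DsdProgram()
        sets = classify_species(prog)
        assert all(len(s) == 0 for s in sets.values())

    def test_signal_species_in_no_set(self):
        prog = compile_crn(uni_catalysis_crn())
        for s in prog.signals:
            assert s not in prog.set_as | prog.set_is | prog.set_iw

    def test_stray_species_detected(self):
        prog = compile_crn(uni_catalysis_crn())
        prog.reactions.append(Reaction({"Mystery": 1}, {}, 1.0))
        with pytest.raises(ValueError):
            classify_species(prog)


class TestRateMap:
    def test_unimolecular_rate_conversion(self):
        # k = 3.0e-3 /s with Cmax = 1000 nM -> qi = 3.0e-6 /nM/s
        crn = CRN()
        crn.add_species("A", initial=1.0)
        crn.add_reaction({"A": 1}, {}, 3.0e-3)
        prog = compile_crn(crn)
        table = rate_map_check(crn, prog)
        assert table.loc[0, "qi"] == pytest.approx(3.0e-6)
        assert bool(table.loc[0, "qi_feasible"])

    def test_infeasible_rate_raises(self):
        crn = CRN()
        crn.add_species("A", initial=1.0)
        crn.add_species("B", initial=1.0)
        crn.add_reaction({"A": 1, "B": 1}, {}, 1.0)  # qi = 1 > qmax = 0.01
        with pytest.raises(InfeasibleRateError):
            compile_crn(crn)

    def test_cap_at_qmax_records_event(self):
        crn = CRN()
        crn.add_species("A", initial=1.0)
        crn.add_species("B", initial=1.0)
        crn.add_reaction({"A": 1, "B": 1}, {}, 1.0)
        prog = compile_crn(crn, cap_at_qmax=True)
        assert len(prog.capped) == 1
        assert prog.reactions[0].rate == DEFAULT_QMAX

    def test_zero_rate_degenerate_but_valid(self):
        crn = CRN()
        crn.add_species("A", initial=1.0)
        crn.add_reaction({"A": 1}, {}, 0.0)
        prog = compile_crn(crn)
        assert prog.reactions[0].rate == 0.0


class TestEquivalence:
    def test_unimolecular_catalysis_within_one_percent(self):
        crn = uni_catalysis_crn(k=1e-3)
        prog = compile_crn(crn)
        rep = validate_equivalence(crn, prog, horizon=10 / 1e-3)
        assert rep.passed
        assert max(rep.relative_deviation.values()) <= 0.01

    def test_bimolecular_catalysis_within_one_percent(self):
        crn = CRN()
        crn.clamp("X", 0.8)
        crn.clamp("T", 0.5)
        crn.add_species("C")
        crn.add_reaction({"X": 1, "T": 1}, {"X": 1, "T": 1, "C": 1}, 1e-4)
        crn.add_reaction({"C": 1}, {}, 1e-4)
        prog = compile_crn(crn)
        rep = validate_equivalence(crn, prog, horizon=5 / 1e-4)
        assert rep.passed

    def test_annihilation_within_one_percent(self):
        crn = CRN()
        crn.add_species("A", initial=2.0)
        crn.add_species("B", initial=1.0)
        crn.add_reaction({"A": 1, "B": 1}, {}, 5e-5)
        prog = compile_crn(crn)
        rep = validate_equivalence(crn, prog, horizon=60000.0)
        assert rep.passed

    def test_catalytic_degradation_within_one_percent(self):
        crn = CRN()
        crn.add_species("O", initial=2.0)
        crn.add_species("E", initial=1.0, clamped=True)
        crn.add_reaction({"O": 1, "E": 1}, {"E": 1}, 1e-4)
        prog = compile_crn(crn)
        rep = validate_equivalence(crn, prog, horizon=50000.0)
        assert rep.passed

    def test_trimolecular_within_one_percent(self):
        crn = CRN()
        crn.clamp("X", 0.8)
        crn.clamp("W", 0.63)
        crn.add_species("I", initial=0.5)
        crn.add_reaction({"X": 1, "W": 1, "I": 1}, {"X": 1, "W": 1}, 2e-6)
        prog = compile_crn(crn)
        rep = validate_equivalence(crn, prog, horizon=2e5)
        assert rep.passed

    def test_generic_bimolecular_within_one_percent(self):
        crn = CRN()
        crn.add_species("Sa", initial=2.0)
        crn.add_species("Sb", initial=1.5)
        crn.add_species("Sc")
        crn.add_reaction({"Sa": 1, "Sb": 1}, {"Sc": 1}, 5e-5)
        prog = compile_crn(crn)
        rep = validate_equivalence(crn, prog, horizon=50000.0)
        assert rep.passed

    def test_zero_rate_zero_deviation(self):
        crn = CRN()
        crn.add_species("A", initial=1.0)
        crn.add_reaction({"A": 1}, {}, 0.0)
        prog = compile_crn(crn)
        rep = validate_equivalence(crn, prog, horizon=100.0)
        assert max(rep.max_abs_deviation.values()) == 0.0

    def test_small_cmax_degrades_and_warns(self, caplog):
        crn = uni_catalysis_crn(k=1e-3)
        good = validate_equivalence(crn, compile_crn(crn), horizon=10 / 1e-3)
        with caplog.at_level(logging.WARNING, logger="crnpde"):
            bad = validate_equivalence(crn, compile_crn(crn, cmax=10.0), horizon=10 / 1e-3)
        assert max(bad.relative_deviation.values()) > max(good.relative_deviation.values())
        assert bad.warnings  # auxiliary depletion below 50% of Cmax


class TestScriptExport:
    def test_roundtrip_identity(self):
        prog = compile_crn(uni_catalysis_crn())
        script = export_dsd_script(prog)
        back = parse_dsd_script(script)
        assert back.reactions == prog.reactions
        assert back.set_as == prog.set_as
        assert back.set_is == prog.set_is
        assert back.set_iw == prog.set_iw
        assert back.cmax == prog.cmax and back.qmax == prog.qmax

    def test_export_is_deterministic(self):
        a = export_dsd_script(compile_crn(uni_catalysis_crn()))
        b = export_dsd_script(compile_crn(uni_catalysis_crn()))
        assert a == b

    def test_empty_program_header_only(self):
        script = export_dsd_script(DsdProgram())
        assert script.startswith("# dsd program")
        assert "->" not in script
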