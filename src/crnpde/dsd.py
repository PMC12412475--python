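"""Compile ideal CRN reactions into DNA strand-displacement (DSD) templates.

Every ideal reaction expands into a short cascade of bimolecular steps: one
slow step carrying the programmed rate q_i and fast steps at the maximum
strand-displacement rate qmax.  Rate maps:

* unimolecular-source templates (the slow step pairs the signal with an
  auxiliary held at Cmax):           q_i = k / Cmax
* bimolecular-limited templates:     q_i = k
* trimolecular:                      q_i = k * Cmax

Auxiliary species (Set_AS) start at Cmax; intermediates (Set_IS) shuttle;
inert wastes (Set_IW) only accumulate.  In ``buffered`` mode (default) the
coproduct of each reversible slow step is also initialized at Cmax and
classed as auxiliary, which is what makes the printed bimolecular rate map
q_i = k kinetically exact; with ``buffered=False`` the cascades are emitted
in their literal printed form (coproducts inert, classified as waste).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import CRN, Reaction, simulate

__all__ = [
    "DsdProgram",
    "EquivalenceReport",
    "UnsupportedReactionError",
    "InfeasibleRateError",
    "compile_crn",
    "compile_reaction",
    "classify_species",
    "rate_map_check",
    "validate_equivalence",
    "export_dsd_script",
    "parse_dsd_script",
]

log = logging.getLogger("crnpde")

DEFAULT_CMAX = 1000.0  # nM
DEFAULT_QMAX = 1e-2  # /nM/s  (= 1e7 /M/s)


class UnsupportedReactionError(ValueError):
    pass


class InfeasibleRateError(ValueError):
    """A programmed slow-step rate exceeds the maximum displacement rate."""


@dataclass
class DsdProgram:
    reactions: list[Reaction] = field(default_factory=list)
    set_as: set[str] = field(default_factory=set)  # auxiliary, start at Cmax
    set_is: set[str] = field(default_factory=set)  # intermediates
    set_iw: set[str] = field(default_factory=set)  # inert waste
    signals: set[str] = field(default_factory=set)
    cmax: float = DEFAULT_CMAX
    qmax: float = DEFAULT_QMAX
    rate_table: list[dict] = field(default_factory=list)  # per ideal reaction
    capped: list[str] = field(default_factory=list)

    def to_crn(self, ideal: CRN) -> CRN:
        crn = CRN("dsd_program")
        for name, sp in ideal.species.items():
            crn.add_species(name, ideal.initial.get(name, 0.0), sp.role, sp.clamped)
        for name in sorted(self.set_as):
            crn.add_species(name, initial=self.cmax, role="auxiliary")
        for name in sorted(self.set_is):
            crn.add_species(name, role="intermediate")
        for name in sorted(self.set_iw):
            crn.add_species(name, role="waste")
        for rxn in self.reactions:
            crn.add_reaction(rxn.reactants, rxn.products, rxn.rate, rxn.reverse_rate)
        crn.drives.update(ideal.drives)
        return crn


@dataclass
class EquivalenceReport:
    max_abs_deviation: dict[str, float]
    relative_deviation: dict[str, float]
    horizon: float
    tol: float
    passed: bool
    warnings: list[str] = field(default_factory=list)


class _Namer:
    def __init__(self) -> None:
        self.counter = 0

    def fresh(self, stem: str) -> str:
        self.counter += 1
        return f"{stem}{self.counter}"


def _q(program: DsdProgram, k: float, kind: str) -> float:
    if kind == "uni":
        q = k / program.cmax
    elif kind == "bi":
        q = k
    elif kind == "tri":
        q = k * program.cmax
    else:  # pragma: no cover
        raise ValueError(kind)
    return q


def _check_q(program: DsdProgram, q: float, cap: bool, label: str) -> float:
    if q > program.qmax:
        if not cap:
            raise InfeasibleRateError(
                f"{label}: q_i = {q:g} /nM/s exceeds qmax = {program.qmax:g} /nM/s"
            )
        program.capped.append(label)
        log.warning("%s: q_i %g capped at qmax %g", label, q, program.qmax)
        return program.qmax
    return q


def compile_reaction(
    rxn: Reaction,
    program: DsdProgram,
    namer: _Namer,
    buffered: bool = True,
    cap_at_qmax: bool = False,
) -> list[Reaction]:
    """Expand one ideal reaction into its DSD step list (appended to program)."""
    qmax = program.qmax
    steps: list[Reaction] = []
    label = repr(rxn)
    waste = "Waste"
    program.set_iw.add(waste)

    def aux(stem: str) -> str:
        n = namer.fresh(stem)
        program.set_as.add(n)
        return n

    def mid(stem: str) -> str:
        n = namer.fresh(stem)
        program.set_is.add(n)
        return n

    def co(stem: str) -> str:
        # reversible-slow-step coproduct: buffer (auxiliary) or inert waste
        n = namer.fresh(stem)
        (program.set_as if buffered else program.set_iw).add(n)
        return n

    reac = list(rxn.reactants.elements())
    prods = dict(rxn.products)
    order = rxn.order

    if rxn.reversible:
        # adjustment template: kept verbatim, q_ai = k_ai, q_bi = k_bi
        qf = _check_q(program, rxn.rate, cap_at_qmax, label)
        qr = _check_q(program, rxn.reverse_rate, cap_at_qmax, label)
        steps.append(Reaction(rxn.reactants, rxn.products, qf, qr))
        program.rate_table.append(
            {"reaction": label, "template": "adjustment", "k": rxn.rate, "qi": qf,
             "effective": qf}
        )
        program.reactions.extend(steps)
        return steps

    if order == 0:
        raise UnsupportedReactionError(f"{label}: zeroth-order source has no template")

    if order == 1 and not prods:
        # degradation: Dau+ + Mn ->(qi) 0,  qi = k/Cmax
        q = _check_q(program, _q(program, rxn.rate, "uni"), cap_at_qmax, label)
        m = aux("Mn")
        steps.append(Reaction({reac[0]: 1, m: 1}, {}, q))
        template = "degradation"
    elif order == 1:
        # unimolecular catalysis/source: three-step cascade, qi = k/Cmax
        q = _check_q(program, _q(program, rxn.rate, "uni"), cap_at_qmax, label)
        aa, cstar, ac = aux("Aa"), aux("Cs"), aux("Ac")
        bstar, ab = mid("Bs"), mid("Ab")
        steps.append(Reaction({reac[0]: 1, aa: 1}, {bstar: 1, waste: 1}, q))
        steps.append(Reaction({bstar: 1, cstar: 1}, {ab: 1, waste: 1}, qmax))
        steps.append(Reaction({ab: 1, ac: 1}, {**prods, waste: 1}, qmax))
        template = "catalysis1" if reac[0] in prods else "generic_unimolecular"
    elif order == 2 and not prods:
        # annihilation: A + Qa <-> Ci + Qb ; Qb + B -> Waste,  qi = k
        q = _check_q(program, _q(program, rxn.rate, "bi"), cap_at_qmax, label)
        qa = aux("Qa")
        ci = co("Ci")
        qb = mid("Qb")
        a, bsp = reac
        steps.append(Reaction({a: 1, qa: 1}, {ci: 1, qb: 1}, q, qmax))
        steps.append(Reaction({qb: 1, bsp: 1}, {waste: 1}, qmax))
        template = "annihilation"
    elif order == 2 and len(rxn.reactants) == 2 and rxn.products == _catalyst_only(rxn):
        # catalytic degradation X + E ->(k) E : Eq-75-style chain, qi = k.
        # Literal form keeps the printed reversible middle step; the buffered
        # form commits after the catalyst engages (the (qmax, qmax) middle
        # step would return half the committed flux).
        q = _check_q(program, _q(program, rxn.rate, "bi"), cap_at_qmax, label)
        cat = next(iter(rxn.products))
        victim = next(n for n in rxn.reactants if n != cat)
        oa, od = aux("Oa"), aux("Od")
        ci = co("Ci")
        ob, di = mid("Ob"), mid("Di")
        oc = namer.fresh("Oc")
        program.set_iw.add(oc)
        steps.append(Reaction({victim: 1, oa: 1}, {ci: 1, ob: 1}, q, qmax))
        steps.append(
            Reaction({ob: 1, cat: 1}, {di: 1, oc: 1}, qmax, None if buffered else qmax)
        )
        steps.append(Reaction({di: 1, od: 1}, {cat: 1, waste: 1}, qmax))
        template = "degradation"
    elif order == 2:
        # bimolecular (catalysis2 / generic), qi = k: reversible engagement of
        # the first reactant, then committed steps
        q = _check_q(program, _q(program, rxn.rate, "bi"), cap_at_qmax, label)
        a, bsp = reac
        an = aux("An")
        eai = co("Ea")
        ebi = mid("Eb")
        steps.append(Reaction({a: 1, an: 1}, {eai: 1, ebi: 1}, q, qmax))
        if buffered:
            steps.append(Reaction({bsp: 1, ebi: 1}, {**prods, waste: 1}, qmax))
        else:
            dci, ddi = aux("Dc"), aux("Dd")
            eci, gci = mid("Ec"), mid("Gc")
            steps.append(Reaction({bsp: 1, ebi: 1}, {eci: 1, waste: 1}, qmax))
            steps.append(Reaction({eci: 1, dci: 1}, {gci: 1, waste: 1}, qmax))
            steps.append(Reaction({gci: 1, ddi: 1}, {**prods, waste: 1}, qmax))
        template = (
            "catalysis2" if any(n in prods for n in rxn.reactants) else "generic_bimolecular"
        )
    elif order == 3:
        # trimolecular, qi = k*Cmax: every signal engagement but the last is
        # reversible against a buffered coproduct
        q = _check_q(program, _q(program, rxn.rate, "tri"), cap_at_qmax, label)
        a, bsp, csp = reac
        an = aux("An")
        hai, hci = co("Ha"), co("Hc")
        hbi, bi = mid("Hb"), mid("Bi")
        steps.append(Reaction({a: 1, an: 1}, {hai: 1, hbi: 1}, q, qmax))
        steps.append(Reaction({hbi: 1, bsp: 1}, {bi: 1, hci: 1}, qmax, qmax))
        if buffered:
            steps.append(Reaction({bi: 1, csp: 1}, {**prods, waste: 1}, qmax))
        else:
            hdi = aux("Hd")
            hei = mid("He")
            steps.append(Reaction({bi: 1, hdi: 1}, {hei: 1, waste: 1}, qmax))
            steps.append(Reaction({hei: 1, csp: 1}, {**prods, waste: 1}, qmax))
        template = "catalysis1"
    else:  # pragma: no cover
        raise UnsupportedReactionError(f"{label}: no template for order {order}")

    program.rate_table.append(
        {"reaction": label, "template": template, "k": rxn.rate, "qi": q,
         "effective": q * (program.cmax if order == 1 else 1.0 / (program.cmax if order == 3 else 1.0))}
    )
    program.reactions.extend(steps)
    return steps


def _catalyst_only(rxn: Reaction):
    """Products == one of the reactants (pure catalytic degradation pattern)."""
    from collections import Counter

    for name in rxn.reactants:
        if rxn.products == Counter({name: 1}) and rxn.reactants[name] == 1:
            return rxn.products
    return None


def compile_crn(
    ideal: CRN,
    cmax: float = DEFAULT_CMAX,
    qmax: float = DEFAULT_QMAX,
    buffered: bool = True,
    cap_at_qmax: bool = False,
) -> DsdProgram:
    """Compile every reaction of an ideal CRN into one DSD program."""
    program = DsdProgram(cmax=cmax, qmax=qmax)
    program.signals = set(ideal.species)
    namer = _Namer()
    for rxn in ideal.reactions:
        compile_reaction(rxn, program, namer, buffered=buffered, cap_at_qmax=cap_at_qmax)
    return program


def classify_species(program: DsdProgram) -> dict[str, set[str]]:
    """Return the three disjoint non-signal species sets and check coverage."""
    sets = {"Set_AS": program.set_as, "Set_IS": program.set_is, "Set_IW": program.set_iw}
    seen: set[str] = set()
    for rxn in program.reactions:
        seen |= rxn.species_names()
    non_signal = seen - program.signals
    covered = program.set_as | program.set_is | program.set_iw
    stray = non_signal - covered
    if stray:
        raise ValueError(f"species match no classification: {sorted(stray)}")
    if (program.set_as & program.set_is) or (program.set_as & program.set_iw) or (
        program.set_is & program.set_iw
    ):
        raise ValueError("classification sets are not disjoint")
    return sets


def rate_map_check(ideal: CRN, program: DsdProgram):
    """Per-reaction table of ideal vs programmed vs effective rates."""
    import pandas as pd

    rows = []
    for entry in program.rate_table:
        rows.append(
            {
                "reaction": entry["reaction"],
                "template": entry["template"],
                "ideal_k": entry["k"],
                "qi": entry["qi"],
                "qi_feasible": entry["qi"] <= program.qmax,
            }
        )
    return pd.DataFrame(rows)


def validate_equivalence(
    ideal: CRN,
    program: DsdProgram,
    horizon: float,
    tol: float = 0.01,
    n_points: int = 300,
    signals: list[str] | None = None,
    rtol: float = 1e-8,
) -> EquivalenceReport:
    """Simulate ideal and compiled systems; compare signal trajectories.

    ``tol`` applies to the deviation relative to each signal's dynamic range
    over the horizon (falling back to its max magnitude for flat signals).
    """
    if signals is None:
        signals = sorted(
            n for n in program.signals
            if not ideal.species[n].clamped and n not in ideal.drives
        )
    traj_i = simulate(ideal, horizon, n_points=n_points, check_steady=False, rtol=rtol)
    compiled = program.to_crn(ideal)
    traj_c = simulate(compiled, horizon, n_points=n_points, check_steady=False, rtol=rtol)
    dev: dict[str, float] = {}
    rel: dict[str, float] = {}
    for name in signals:
        d = float(np.abs(traj_i[name] - traj_c[name]).max())
        vals = traj_i[name]
        scale = max(float(vals.max() - vals.min()), float(np.abs(vals).max()), 1e-12)
        dev[name] = d
        rel[name] = d / scale
    warnings = []
    for name in sorted(program.set_as):
        if traj_c.final(name) < 0.5 * program.cmax:
            warnings.append(
                f"auxiliary {name} depleted below 50% of Cmax "
                f"({traj_c.final(name):.1f} nM)"
            )
    for w in warnings:
        log.warning("%s", w)
    passed = bool(all(v <= tol for v in rel.values()))
    return EquivalenceReport(dev, rel, horizon, tol, passed, warnings)


# ---------------------------------------------------------------------------
# deterministic script interchange


def export_dsd_script(program: DsdProgram) -> str:
    """Deterministic text listing; re-parsing reproduces the program exactly."""
    lines = ["# dsd program", f"# cmax: {program.cmax!r}", f"# qmax: {program.qmax!r}"]
    for key, names in (
        ("signal", program.signals),
        ("auxiliary", program.set_as),
        ("intermediate", program.set_is),
        ("waste", program.set_iw),
    ):
        for n in sorted(names):
            lines.append(f"# {key}: {n}")
    for rxn in program.reactions:
        lines.append(repr(rxn))
    return "\n".join(lines) + "\n"


def parse_dsd_script(text: str) -> DsdProgram:
    from .textfmt import parse_crn

    program = DsdProgram()
    crn_lines = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("cmax:"):
                program.cmax = float(body[5:])
            elif body.startswith("qmax:"):
                program.qmax = float(body[5:])
            elif body.startswith("signal:"):
                program.signals.add(body[7:].strip())
            elif body.startswith("auxiliary:"):
                program.set_as.add(body[10:].strip())
            elif body.startswith("intermediate:"):
                program.set_is.add(body[13:].strip())
            elif body.startswith("waste:"):
                program.set_iw.add(body[6:].strip())
            continue
        crn_lines.append(line)
    crn = parse_crn("\n".join(crn_lines))
    program.reactions = list(crn.reactions)
    return program
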