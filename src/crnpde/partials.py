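"""Division-principle CRNs for partial derivatives of monomial sums.

A monomial accumulation species B reaches steady value coeff * prod(v^e) by
catalytic production against paired degradation.  The division module

    B -> B + O     (rate e * k)
    X + O -> X     (rate k)

has steady [O] = e * [B] / [X], which is exactly the partial-derivative
contribution of the term; with the rate ratio set to the product of two
exponents and both variables consuming, the same motif yields mixed partials.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import sympy

from .core import CRN, CRNError

__all__ = [
    "MonomialTerm",
    "build_monomial_crn",
    "build_partial_crn",
    "build_mixed_partial_crn",
    "build_adder",
    "polynomial_crn",
    "symbolic_partial",
]

#: variables below this (nM) reject division-module construction
SINGULARITY_FLOOR = 1e-3

DEFAULT_K = 6.0e-4  # Table-like nominal rate for the partial modules


@dataclass(frozen=True)
class MonomialTerm:
    coefficient: float
    exponents: tuple[tuple[str, int], ...]  # sorted (variable, exponent>0) pairs

    @classmethod
    def make(cls, coefficient: float, exponents: dict[str, int]) -> "MonomialTerm":
        if coefficient < 0:
            raise ValueError("coefficients must be nonnegative (sign lives on the dual rail)")
        exps = tuple(sorted((v, e) for v, e in exponents.items() if e > 0))
        if any(e < 0 for _, e in exps):
            raise ValueError("exponents must be nonnegative integers")
        if sum(e for _, e in exps) > 4:
            raise ValueError("total degree > 4 unsupported")
        return cls(coefficient, exps)

    @property
    def degree(self) -> int:
        return sum(e for _, e in self.exponents)

    def exponent(self, var: str) -> int:
        return dict(self.exponents).get(var, 0)

    def evaluate(self, values: dict[str, float]) -> float:
        out = self.coefficient
        for v, e in self.exponents:
            out *= values[v] ** e
        return out

    def expr(self) -> sympy.Expr:
        out = sympy.Float(self.coefficient)
        for v, e in self.exponents:
            out *= sympy.Symbol(v) ** e
        return out


def build_monomial_crn(
    term: MonomialTerm,
    k: float,
    output: str,
    values: dict[str, float] | None = None,
) -> CRN:
    """CRN whose ``output`` settles at the term's value with variables clamped.

    Degree <= 3 compiles to a single catalytic production at coefficient*k
    (reactant multiplicities = exponents) with paired degradation at k.
    Degree-4 terms split through an intermediate product stage, since
    mass-action order is capped at 3; the steady value is unchanged.
    """
    crn = CRN(f"monomial_{output}")
    if values:
        for v, val in values.items():
            crn.clamp(v, val)
    cat = {v: e for v, e in term.exponents}
    if term.degree > 3:
        # split: inner product species at value prod v^(e_inner), then the rest
        inner = f"{output}_i"
        flat = list(
            itertools.chain.from_iterable([v] * e for v, e in term.exponents)
        )
        inner_vars, outer_vars = flat[:2], flat[2:]
        c_inner: dict[str, int] = {}
        for v in inner_vars:
            c_inner[v] = c_inner.get(v, 0) + 1
        crn.add_reaction(c_inner, {**c_inner, inner: 1}, k)
        crn.add_reaction({inner: 1}, {}, k)
        c_outer: dict[str, int] = {inner: 1}
        for v in outer_vars:
            c_outer[v] = c_outer.get(v, 0) + 1
        crn.add_reaction(c_outer, {**c_outer, output: 1}, term.coefficient * k)
        crn.add_reaction({output: 1}, {}, k)
    else:
        crn.add_reaction(cat, {**cat, output: 1}, term.coefficient * k)
        crn.add_reaction({output: 1}, {}, k)
    crn.species[output] = type(crn.species[output])(output, "output", False)
    return crn


def _guard(values: dict[str, float] | None, var: str) -> None:
    if values is not None:
        val = values.get(var)
        if val is not None and val < SINGULARITY_FLOOR:
            raise CRNError(
                f"variable {var} = {val} below singularity floor {SINGULARITY_FLOOR} nM; "
                "division-module steady state ~ 1/[{var}]"
            )


def build_partial_crn(
    term_species: str,
    variable: str,
    exponent: int,
    k: float,
    output: str,
    values: dict[str, float] | None = None,
) -> CRN:
    """Division module: steady [output] = exponent * [term_species] / [variable]."""
    crn = CRN(f"partial_{output}")
    if exponent < 1:
        return crn  # exponent-0 term contributes nothing; no CRN emitted
    _guard(values, variable)
    crn.add_reaction({term_species: 1}, {term_species: 1, output: 1}, exponent * k)
    crn.add_reaction({variable: 1, output: 1}, {variable: 1}, k)
    crn.species[output] = type(crn.species[output])(output, "output", False)
    return crn


def build_mixed_partial_crn(
    term_species: str,
    var_pair: tuple[str, str],
    exponents: tuple[int, int],
    k: float,
    output: str,
    values: dict[str, float] | None = None,
) -> CRN:
    """Mixed partial: steady [output] = ex*et*[term]/([x][t])."""
    crn = CRN(f"mixed_partial_{output}")
    ex, et = exponents
    if ex < 1 or et < 1:
        return crn
    x, t = var_pair
    _guard(values, x)
    _guard(values, t)
    crn.add_reaction({term_species: 1}, {term_species: 1, output: 1}, ex * et * k)
    crn.add_reaction({x: 1, t: 1, output: 1}, {x: 1, t: 1}, k)
    crn.species[output] = type(crn.species[output])(output, "output", False)
    return crn


def build_adder(inputs: list[str], output: str, k: float) -> CRN:
    """Catalytic fan-in at k with degradation at k: steady output = sum(inputs)."""
    crn = CRN(f"adder_{output}")
    crn.add_species(output, role="output")
    for name in inputs:
        crn.add_reaction({name: 1}, {name: 1, output: 1}, k)
    crn.add_reaction({output: 1}, {}, k)
    return crn


@dataclass
class PolynomialChannels:
    """Species naming for a compiled monomial sum and its partials."""

    value: str
    terms: list[str] = field(default_factory=list)
    partials: dict[str, str] = field(default_factory=dict)  # variable -> sum species


def polynomial_crn(
    terms: list[MonomialTerm],
    values: dict[str, float],
    k: float = DEFAULT_K,
    prefix: str = "F",
    wrt: list[str] | None = None,
) -> tuple[CRN, PolynomialChannels]:
    """Compile a monomial sum: value channel plus first-order partial channels.

    Variables are clamped at ``values``; ``wrt`` selects the partial channels
    (default: every variable appearing in the terms).
    """
    crn = CRN(f"poly_{prefix}")
    for v, val in values.items():
        crn.clamp(v, val)
    ch = PolynomialChannels(value=f"{prefix}_val")
    term_names = []
    for i, term in enumerate(terms):
        name = f"{prefix}_m{i}"
        crn.merge(build_monomial_crn(term, k, name, None))
        term_names.append(name)
    ch.terms = term_names
    crn.merge(build_adder(term_names, ch.value, k))
    if wrt is None:
        wrt = sorted({v for t in terms for v, _ in t.exponents})
    for var in wrt:
        contribs = []
        for name, term in zip(term_names, terms):
            e = term.exponent(var)
            if e >= 1:
                out = f"{name}_d{var}"
                crn.merge(build_partial_crn(name, var, e, k, out, values))
                contribs.append(out)
        sum_name = f"{prefix}_d{var}"
        crn.merge(build_adder(contribs, sum_name, k))
        ch.partials[var] = sum_name
    return crn, ch


def symbolic_partial(
    terms: list[MonomialTerm],
    values: dict[str, float],
    wrt: tuple[str, ...],
) -> float:
    """Independent oracle: sympy differentiation of the monomial sum."""
    expr = sum((t.expr() for t in terms), sympy.Integer(0))
    for var in wrt:
        expr = sympy.diff(expr, sympy.Symbol(var))
    subs = {sympy.Symbol(v): val for v, val in values.items()}
    return float(expr.subs(subs))
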