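"""Deterministic toy-CRN and target-function fixture generation."""

from __future__ import annotations

import numpy as np

from .brusselator import BrusselatorSpec, build_brusselator_crn
from .core import CRN
from .partials import MonomialTerm

__all__ = ["generate_fixtures", "random_monomial_sum", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("decay", "catalysis", "brusselator-demo", "random-monomial-sum")


def random_monomial_sum(
    rng: np.random.Generator,
    max_terms: int = 4,
    max_exponent: int = 2,
    variables: tuple[str, ...] = ("X", "T"),
) -> tuple[list[MonomialTerm], dict[str, float]]:
    """Random monomial sum with inputs in [0.2, 2] (division-safe range)."""
    n_terms = int(rng.integers(1, max_terms + 1))
    terms = []
    for _ in range(n_terms):
        exps = {v: int(rng.integers(0, max_exponent + 1)) for v in variables}
        if sum(exps.values()) == 0:
            exps[variables[0]] = 1
        coeff = float(np.round(rng.uniform(0.1, 2.0), 3))
        terms.append(MonomialTerm.make(coeff, exps))
    values = {v: float(np.round(rng.uniform(0.2, 2.0), 3)) for v in variables}
    return terms, values


def generate_fixtures(kind: str, seed: int = 0):
    """Deterministic toy systems in the standard CRN data model.

    Returns a CRN for the CRN-shaped kinds and (terms, values) for
    ``random-monomial-sum``.
    """
    rng = np.random.default_rng(seed)
    if kind == "decay":
        crn = CRN("decay")
        crn.add_species("A", initial=1.0)
        crn.add_reaction({"A": 1}, {}, 1e-3)
        return crn
    if kind == "catalysis":
        crn = CRN("catalysis")
        crn.add_species("A", initial=1.0, clamped=True)
        crn.add_species("B")
        crn.add_reaction({"A": 1}, {"A": 1, "B": 1}, 1e-3)
        crn.add_reaction({"B": 1}, {}, 1e-3)
        return crn
    if kind == "brusselator-demo":
        return build_brusselator_crn(BrusselatorSpec.demo())
    if kind == "random-monomial-sum":
        return random_monomial_sum(rng)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
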