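"""Plain-text CRN interchange format.

One reaction per line::

    A + 2 B -> C @ 0.003
    X <-> Y @ 0.01,0.02
    # clamp: A=3.0
    # init: B=1.5

``# clamp:`` declares a held concentration; ``# init:`` a free initial
concentration.  ``0`` stands for the empty multiset on either side.
The writer is deterministic and ``parse(write(crn))`` round-trips exactly.
"""

from __future__ import annotations

import re

from .core import CRN, CRNError

__all__ = ["parse_crn", "write_crn", "read_crn_file", "write_crn_file"]

_TERM = re.compile(r"^\s*(?:(\d+)\s+)?([A-Za-z_][A-Za-z0-9_+\-*']*)\s*$")


def _parse_side(text: str) -> dict[str, int]:
    text = text.strip()
    if text == "0" or not text:
        return {}
    out: dict[str, int] = {}
    for term in text.split(" + "):
        m = _TERM.match(term)
        if not m:
            raise CRNError(f"cannot parse reaction term {term!r}")
        mult = int(m.group(1) or 1)
        name = m.group(2)
        out[name] = out.get(name, 0) + mult
    return out


def parse_crn(text: str, name: str = "crn") -> CRN:
    crn = CRN(name)
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("crn:"):
                crn.name = body[4:].strip()
            elif body.startswith("clamp:"):
                k, v = body[6:].split("=")
                crn.clamp(k.strip(), float(v))
            elif body.startswith("init:"):
                k, v = body[5:].split("=")
                crn.add_species(k.strip(), initial=float(v))
            continue
        try:
            lhs, rest = re.split(r"<->|->", line, maxsplit=1)
            arrow = "<->" if "<->" in line.split("@")[0] else "->"
            body, rates = rest.rsplit("@", 1)
        except ValueError as exc:
            raise CRNError(f"line {lineno}: cannot parse {line!r}") from exc
        reactants = _parse_side(lhs)
        products = _parse_side(body)
        parts = [float(p) for p in rates.split(",")]
        if arrow == "<->":
            if len(parts) != 2:
                raise CRNError(f"line {lineno}: reversible reaction needs kf,kr")
            crn.add_reaction(reactants, products, parts[0], parts[1])
        else:
            if len(parts) != 1:
                raise CRNError(f"line {lineno}: irreversible reaction takes one rate")
            crn.add_reaction(reactants, products, parts[0])
    return crn


def _fmt_side(side) -> str:
    if not side:
        return "0"
    parts = []
    for n in sorted(side):
        m = side[n]
        parts.append(n if m == 1 else f"{m} {n}")
    return " + ".join(parts)


def write_crn(crn: CRN) -> str:
    lines = [f"# crn: {crn.name}"]
    for n in sorted(crn.species):
        if crn.species[n].clamped:
            lines.append(f"# clamp: {n}={crn.initial.get(n, 0.0)!r}")
    for n in sorted(crn.species):
        v = crn.initial.get(n, 0.0)
        if v and not crn.species[n].clamped:
            lines.append(f"# init: {n}={v!r}")
    for rxn in crn.reactions:
        if rxn.reversible:
            lines.append(
                f"{_fmt_side(rxn.reactants)} <-> {_fmt_side(rxn.products)}"
                f" @ {rxn.rate!r},{rxn.reverse_rate!r}"
            )
        else:
            lines.append(f"{_fmt_side(rxn.reactants)} -> {_fmt_side(rxn.products)} @ {rxn.rate!r}")
    return "\n".join(lines) + "\n"


def read_crn_file(path) -> CRN:
    with open(path) as fh:
        return parse_crn(fh.read())


def write_crn_file(crn: CRN, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_crn(crn))
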