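"""CRN oscillator sources emitting offset sine / cosine signals.

The harmonic core is a dual-rail pair (Ap, Am) / (Bp, Bm) with cross-catalysis
at rate ``l`` and fast annihilation, so that [Ap]-[Am] = cos(l t) and
[Bp]-[Bm] = sin(l t).  An output pair integrates one rail of the core,
producing an offset waveform that stays positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CRN

__all__ = ["OscillatorSpec", "build_sine_source", "build_cosine_source", "estimate_period"]


@dataclass(frozen=True)
class OscillatorSpec:
    l: float = 1.0
    fast: float = 1e5
    phase: str = "sine"
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.l <= 0:
            raise ValueError("catalytic rate l must be positive")
        if self.fast / self.l < 1e3:
            raise ValueError("fast/l ratio must be >= 1e3 for clean rail separation")
        if self.phase not in ("sine", "cosine"):
            raise ValueError(f"unknown phase {self.phase!r}")


def build_sine_source(spec: OscillatorSpec) -> CRN:
    """Seven-reaction CRN whose output Ua_ext tracks offset + sin(l t).

    Four catalytic reactions at rate l, three annihilations at rate fast.
    Ub_ext is the annihilation partner (negative lobe) of the output.
    """
    crn = CRN("sine_source")
    l, fast = spec.l, spec.fast
    crn.add_species("Ap", initial=1.0)
    crn.add_species("Am")
    crn.add_species("Bp")
    crn.add_species("Bm")
    crn.add_species("Ua_ext", initial=spec.offset, role="output")
    crn.add_species("Ub_ext")
    crn.add_reaction({"Ap": 1}, {"Ap": 1, "Bp": 1, "Ua_ext": 1}, l)
    crn.add_reaction({"Am": 1}, {"Am": 1, "Bm": 1, "Ub_ext": 1}, l)
    crn.add_reaction({"Bm": 1}, {"Ap": 1, "Bm": 1}, l)
    crn.add_reaction({"Bp": 1}, {"Am": 1, "Bp": 1}, l)
    crn.add_reaction({"Bm": 1, "Bp": 1}, {}, fast)
    crn.add_reaction({"Am": 1, "Ap": 1}, {}, fast)
    crn.add_reaction({"Ua_ext": 1, "Ub_ext": 1}, {}, fast)
    return crn


def build_cosine_source(spec: OscillatorSpec) -> CRN:
    """Seven-reaction CRN whose output Ub_ext tracks (offset+1) + cos(l t) - 1.

    The output integrates the sine rail pair with a sign flip, starting at
    offset + 1 so that the waveform equals offset + cos(l t).
    """
    crn = CRN("cosine_source")
    l, fast = spec.l, spec.fast
    crn.add_species("Ap", initial=1.0)
    crn.add_species("Am")
    crn.add_species("Bp")
    crn.add_species("Bm")
    crn.add_species("Ub_ext", initial=spec.offset + 1.0, role="output")
    crn.add_species("Ua_ext")
    crn.add_reaction({"Ap": 1}, {"Ap": 1, "Bp": 1}, l)
    crn.add_reaction({"Am": 1}, {"Am": 1, "Bm": 1}, l)
    crn.add_reaction({"Bm": 1}, {"Ap": 1, "Bm": 1, "Ub_ext": 1}, l)
    crn.add_reaction({"Bp": 1}, {"Am": 1, "Bp": 1, "Ua_ext": 1}, l)
    crn.add_reaction({"Bm": 1, "Bp": 1}, {}, fast)
    crn.add_reaction({"Am": 1, "Ap": 1}, {}, fast)
    crn.add_reaction({"Ua_ext": 1, "Ub_ext": 1}, {}, fast)
    return crn


def build_source(spec: OscillatorSpec) -> CRN:
    return build_sine_source(spec) if spec.phase == "sine" else build_cosine_source(spec)


def output_species(spec: OscillatorSpec) -> str:
    return "Ua_ext" if spec.phase == "sine" else "Ub_ext"


def estimate_period(times: np.ndarray, values: np.ndarray, level: float) -> float:
    """Period from successive upward crossings of ``level`` (linear interp)."""
    times = np.asarray(times)
    values = np.asarray(values)
    shifted = values - level
    crossings = []
    for i in range(len(shifted) - 1):
        if shifted[i] < 0 <= shifted[i + 1]:
            frac = -shifted[i] / (shifted[i + 1] - shifted[i])
            crossings.append(times[i] + frac * (times[i + 1] - times[i]))
    if len(crossings) < 2:
        raise ValueError("fewer than two upward crossings; extend the horizon")
    return float(np.mean(np.diff(crossings)))
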