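"""Membrane-diffusion derivative CRNs.

An external signal crosses a "membrane" at rate kdiff, creating a lagged
internal copy; the activation/annihilation stage converts the scaled
difference kdiff*(external - internal) into a dual-rail derivative estimate,
and a five-reaction subtraction block reads it out on the (Umm, Unn) pair.
The estimate approximates the backward difference
(U(t-eps) - U(t-tau-eps))/tau with tau = 1/kdiff and eps = 1/k.

The nominal rates (kdiff = 4.0e-4 /s) give a very coarse differentiator
(tau = 2500 s); :meth:`DifferentiatorConfig.fast_regime` scales every rate so
the closed-form validation against cos/-sin is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .core import CRN

__all__ = [
    "DifferentiatorConfig",
    "build_first_order",
    "build_subtraction",
    "build_second_order",
    "chain_rule_integrator",
]


@dataclass(frozen=True)
class DifferentiatorConfig:
    kdiff: float = 4.0e-4
    k: float = 3.0e-3
    kfast: float = 10.0
    alpha_a: float = 5.0e-4
    beta_a: float = 5.0e-4
    delta_a: float = 5.0e-4
    gamma_a: float = 1.0
    kdiff2: float | None = None  # second stage; defaults to kdiff

    def __post_init__(self) -> None:
        for name in ("kdiff", "k", "kfast", "alpha_a", "beta_a", "delta_a", "gamma_a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.alpha_a == self.beta_a == self.delta_a):
            raise ValueError(
                "subtraction block requires alpha_a = beta_a = delta_a "
                "(steady-state identity assumption)"
            )

    @property
    def kdiff2_(self) -> float:
        return self.kdiff if self.kdiff2 is None else self.kdiff2

    @property
    def tau(self) -> float:
        return 1.0 / self.kdiff

    @property
    def eps(self) -> float:
        return 1.0 / self.k

    @classmethod
    def fast_regime(cls, kdiff: float) -> "DifferentiatorConfig":
        """Rates for closed-form validation: every lag scales as 1/kdiff."""
        s = 20.0 * kdiff
        return cls(
            kdiff=kdiff,
            k=s,
            kfast=50.0 * s,
            alpha_a=s,
            beta_a=s,
            delta_a=s,
            gamma_a=500.0 * s,
            kdiff2=kdiff,
        )

    def second_stage(self) -> "DifferentiatorConfig":
        return replace(self, kdiff=self.kdiff2_, kdiff2=self.kdiff2_)


def build_subtraction(
    cfg: DifferentiatorConfig,
    in_plus: str = "Dau_p",
    in_minus: str = "Dau_m",
    out_plus: str = "Umm",
    out_minus: str = "Unn",
) -> CRN:
    """Five-reaction block: steady (out_plus - out_minus) = in_plus - in_minus.

    With nonnegative inputs and the fast annihilation, the larger input lands
    on out_plus and the smaller branch decays to ~0.
    """
    crn = CRN("subtraction")
    crn.add_reaction({in_plus: 1}, {in_plus: 1, out_plus: 1}, cfg.alpha_a)
    crn.add_reaction({in_minus: 1}, {in_minus: 1, out_minus: 1}, cfg.beta_a)
    crn.add_reaction({out_plus: 1}, {}, cfg.delta_a)
    crn.add_reaction({out_minus: 1}, {}, cfg.delta_a)
    crn.add_reaction({out_plus: 1, out_minus: 1}, {}, cfg.gamma_a)
    crn.species[out_plus] = crn.species[out_plus].__class__(out_plus, "output", False)
    crn.species[out_minus] = crn.species[out_minus].__class__(out_minus, "output", False)
    return crn


def build_first_order(
    cfg: DifferentiatorConfig,
    input_species: str = "Ua_ext",
    tag: str = "",
    u0: float | None = None,
) -> CRN:
    """The 12-reaction first-order differentiator for ``input_species``.

    Membrane transfer (2), dual-rail activation (4), fast annihilation (1),
    and the subtraction block (5).  Steady output:
    Umm - Unn = kdiff * ([input] - [internal copy]).

    ``u0`` pre-equilibrates the membrane copy at the input's initial value,
    suppressing the spurious kdiff*u0 start-up spike (essential when the
    output feeds an integrator).
    """
    u_in = f"Ua_in{tag}"
    dau_p, dau_m = f"Dau_p{tag}", f"Dau_m{tag}"
    umm, unn = f"Umm{tag}", f"Unn{tag}"
    crn = CRN(f"differentiator1{tag}")
    crn.add_species(input_species, role="input")
    if u0 is not None:
        crn.add_species(u_in, initial=u0)
    # membrane transfer: lagged internal copy
    crn.add_reaction({input_species: 1}, {input_species: 1, u_in: 1}, cfg.kdiff)
    crn.add_reaction({u_in: 1}, {}, cfg.kdiff)
    # activation of the dual-rail difference pair
    crn.add_reaction({input_species: 1}, {input_species: 1, dau_p: 1}, cfg.k * cfg.kdiff)
    crn.add_reaction({dau_p: 1}, {}, cfg.k)
    crn.add_reaction({u_in: 1}, {u_in: 1, dau_m: 1}, cfg.k * cfg.kdiff)
    crn.add_reaction({dau_m: 1}, {}, cfg.k)
    crn.add_reaction({dau_p: 1, dau_m: 1}, {}, cfg.kfast)
    crn.merge(build_subtraction(cfg, dau_p, dau_m, umm, unn))
    return crn


def build_second_order(
    cfg: DifferentiatorConfig, input_species: str = "Ua_ext"
) -> CRN:
    """First-order stage cascaded into a second membrane/differentiator stage.

    The first stage's output pair (Dmm, Dnn) feeds a dual-rail membrane whose
    lagged copy is (Ua_core_p, Ua_core_m); steady second-order output:
    Omm - Onn = kdiff2 * ((Dmm - Dnn) - (Ua_core_p - Ua_core_m)).
    """
    cfg2 = cfg.second_stage()
    kd2, k = cfg2.kdiff, cfg.k
    crn = build_first_order(cfg, input_species)
    # rename the first-stage outputs to the second-stage input pair
    stage1 = build_subtraction(cfg, f"Dau_p", f"Dau_m", "Dmm", "Dnn")
    crn.reactions = [r for r in crn.reactions if "Umm" not in r.species_names() and "Unn" not in r.species_names()]
    for name in ("Umm", "Unn"):
        crn.species.pop(name, None)
        crn.initial.pop(name, None)
    crn.merge(stage1)
    # dual-rail membrane: lagged copy of the first derivative
    crn.add_reaction({"Dmm": 1}, {"Dmm": 1, "Ua_core_p": 1}, kd2)
    crn.add_reaction({"Ua_core_p": 1}, {}, kd2)
    crn.add_reaction({"Dnn": 1}, {"Dnn": 1, "Ua_core_m": 1}, kd2)
    crn.add_reaction({"Ua_core_m": 1}, {}, kd2)
    # signed activation: external rails excite same-sign, lagged rails opposite
    crn.add_reaction({"Dmm": 1}, {"Dmm": 1, "Oau_p": 1}, k * kd2)
    crn.add_reaction({"Dnn": 1}, {"Dnn": 1, "Oau_m": 1}, k * kd2)
    crn.add_reaction({"Ua_core_p": 1}, {"Ua_core_p": 1, "Oau_m": 1}, k * kd2)
    crn.add_reaction({"Ua_core_m": 1}, {"Ua_core_m": 1, "Oau_p": 1}, k * kd2)
    crn.add_reaction({"Oau_p": 1}, {}, k)
    crn.add_reaction({"Oau_m": 1}, {}, k)
    crn.add_reaction({"Oau_p": 1, "Oau_m": 1}, {}, cfg.kfast)
    crn.merge(build_subtraction(cfg2, "Oau_p", "Oau_m", "Omm", "Onn"))
    crn.name = "differentiator2"
    return crn


def chain_rule_integrator(
    cfg: DifferentiatorConfig,
    input_species: str = "Ua_ext",
    exponent: int = 2,
    coefficient: float = 1.0,
    y0: float | None = None,
    u0: float | None = None,
) -> CRN:
    """Integrate dY/dt = coefficient * U^exponent * (dU/dt) via the first-order
    derivative estimate, i.e. f'(U) = coefficient * U^exponent.

    Returns the first-order differentiator extended with the (Yp, Ym) pair;
    read Y as [Yp] - [Ym].  Y(0) = f(U(0)) must be supplied via ``y0`` (or the
    input's initial concentration is used to evaluate it).
    """
    if exponent < 0 or exponent > 2:
        raise ValueError("f' must be a monomial of degree <= 2 (reaction order cap)")
    crn = build_first_order(cfg, input_species, u0=u0)
    crn.add_reaction(
        {input_species: exponent, "Umm": 1},
        {input_species: exponent, "Umm": 1, "Yp": 1},
        coefficient,
    )
    crn.add_reaction(
        {input_species: exponent, "Unn": 1},
        {input_species: exponent, "Unn": 1, "Ym": 1},
        coefficient,
    )
    crn.add_reaction({"Yp": 1, "Ym": 1}, {}, cfg.kfast)
    if y0 is None:
        start = u0 if u0 is not None else crn.initial.get(input_species, 0.0)
        y0 = coefficient * start ** (exponent + 1) / (exponent + 1)
    crn.add_species("Yp", initial=max(y0, 0.0), role="output")
    crn.add_species("Ym", initial=max(-y0, 0.0))
    crn.name = "chain_rule_integrator"
    return crn
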