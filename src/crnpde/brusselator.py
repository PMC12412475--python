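"""Brusselator CRN, reduced-PDE residual network, and error assembly.

The reduced first Brusselator equation at a clamped evaluation point is

    R11 = dU/dt - Du * d2U/dx2 - kc*V'*U^2 - ka*A' + (kb*B' + kd)*U

carried on a dual-rail (R11p, R11m) pair; a squaring channel relaxes to
Error2 = R11^2 and a magnitude channel to |R11| (both readouts are exposed
because the nominal error tables mix the two scales).  Error1 is the
magnitude of the network-vs-target mismatch, and Loss = Error1 + Error2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import sympy

from .ann import NetworkSpec, coefficients, train
from .core import CRN, Trajectory, simulate, steady_state
from .partials import (
    DEFAULT_K,
    MonomialTerm,
    build_adder,
    build_monomial_crn,
    build_partial_crn,
)

__all__ = [
    "BrusselatorSpec",
    "VerificationSpec",
    "ErrorReport",
    "build_brusselator_crn",
    "brusselator_fixed_point",
    "build_target_function_crn",
    "build_error_comparator",
    "build_square_channel",
    "build_pde_residual_crn",
    "assemble_loss",
    "analytic_residual",
    "worked_example",
    "assemble_full_system",
    "PipelineResult",
]

log = logging.getLogger("crnpde")


@dataclass(frozen=True)
class BrusselatorSpec:
    ka: float = 1.0
    kb: float = 0.3
    kc: float = 0.2
    kd: float = 0.1
    A0: float = 3.0
    B0: float = 3.0
    Du: float = 0.5
    A_prime: float = 2.0
    B_prime: float = 2.0
    V_prime: float = 1.0

    def __post_init__(self) -> None:
        for r in ("ka", "kb", "kc", "kd"):
            if getattr(self, r) <= 0:
                raise ValueError(f"{r} must be a non-negative non-zero rate")

    @classmethod
    def demo(cls) -> "BrusselatorSpec":
        """Kinetic demo parameterization (3 nM inputs)."""
        return cls(ka=0.003, kb=0.002, kc=0.01, kd=0.001, A0=3.0, B0=3.0)


@dataclass(frozen=True)
class VerificationSpec:
    a: float = 1.0
    b: float = 2.0
    c: float = 0.5
    x0: float = 0.8
    t0: float = 0.5

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("a, b, c must be > 0")

    def terms(self) -> list[MonomialTerm]:
        return [
            MonomialTerm.make(self.a, {"X": 2}),
            MonomialTerm.make(self.b, {"T": 2}),
            MonomialTerm.make(self.c, {"X": 1, "T": 1}),
        ]

    def value(self) -> float:
        return self.a * self.x0**2 + self.b * self.t0**2 + self.c * self.x0 * self.t0


@dataclass
class ErrorReport:
    Error1: float
    Error2: float
    Loss: float
    R11: float

    def __post_init__(self) -> None:
        if min(self.Error1, self.Error2, self.Loss) < -1e-9:
            raise ValueError("error channels must be nonnegative")


# ---------------------------------------------------------------------------
# the Brusselator itself


def build_brusselator_crn(spec: BrusselatorSpec, x0: float = 0.0, y0: float = 0.0) -> CRN:
    """Classical four-reaction Brusselator with clamped feeds A, B."""
    crn = CRN("brusselator")
    crn.clamp("A", spec.A0)
    crn.clamp("B", spec.B0)
    crn.add_species("Xp", initial=x0)
    crn.add_species("Yp", initial=y0)
    crn.add_reaction({"A": 1}, {"A": 1, "Xp": 1}, spec.ka)
    crn.add_reaction({"B": 1, "Xp": 1}, {"B": 1, "Yp": 1, "Dw": 1}, spec.kb)
    crn.add_reaction({"Xp": 2, "Yp": 1}, {"Xp": 3}, spec.kc)
    crn.add_reaction({"Xp": 1}, {}, spec.kd)
    crn.species["Dw"] = type(crn.species["Dw"])("Dw", "waste", False)
    return crn


def brusselator_fixed_point(spec: BrusselatorSpec) -> tuple[float, float]:
    """Homogeneous fixed point: X* = ka*A/kd, Y* = kb*B/(kc*X*)."""
    xs = spec.ka * spec.A0 / spec.kd
    ys = spec.kb * spec.B0 / (spec.kc * xs)
    return xs, ys


# ---------------------------------------------------------------------------
# verification module


def build_target_function_crn(v: VerificationSpec, k: float = DEFAULT_K) -> CRN:
    """Monomial CRNs for a x^2, b t^2, c x t summed into P*."""
    crn = CRN("target_function")
    values = {"X": v.x0, "T": v.t0}
    names = []
    for i, term in enumerate(v.terms()):
        name = f"Pstar_m{i}"
        crn.merge(build_monomial_crn(term, k, name, values))
        names.append(name)
    crn.merge(build_adder(names, "Pstar", k))
    return crn


def build_error_comparator(
    p_species: str,
    pstar_species: str,
    k: float = DEFAULT_K,
    gamma: float = 1.0,
    out: str = "Error1",
) -> CRN:
    """Dual-rail subtraction plus magnitude: steady [out] = |P - P*|."""
    crn = CRN("error_comparator")
    ep, em = f"{out}_p", f"{out}_m"
    crn.add_reaction({p_species: 1}, {p_species: 1, ep: 1}, k)
    crn.add_reaction({pstar_species: 1}, {pstar_species: 1, em: 1}, k)
    crn.add_reaction({ep: 1}, {}, k)
    crn.add_reaction({em: 1}, {}, k)
    crn.add_reaction({ep: 1, em: 1}, {}, gamma)
    # magnitude: with the annihilation holding min(ep, em) ~ 0, ep + em = |P-P*|
    crn.add_reaction({ep: 1}, {ep: 1, out: 1}, k)
    crn.add_reaction({em: 1}, {em: 1, out: 1}, k)
    crn.add_reaction({out: 1}, {}, k)
    return crn


def build_square_channel(input_pair: tuple[str, str], out: str, k: float) -> CRN:
    """Relaxation d[out]/dt = k*r^2 - k*[out] for a dual-rail r.

    Squares each rail; the annihilation keeps the minor rail near zero so the
    sum of rail squares tracks r^2.
    """
    crn = CRN(f"square_{out}")
    plus, minus = input_pair
    crn.add_reaction({plus: 2}, {plus: 2, out: 1}, k)
    crn.add_reaction({minus: 2}, {minus: 2, out: 1}, k)
    crn.add_reaction({out: 1}, {}, k)
    return crn


def build_pde_residual_crn(
    b: BrusselatorSpec,
    taps: dict[str, str],
    k: float = DEFAULT_K,
    gamma: float = 1.0,
) -> CRN:
    """Residual channel from steady taps (species names).

    ``taps`` must provide 'dUdt', 'Uxx', 'U', 'U2'.  Positive contributions
    (dU/dt and (kb*B'+kd)*U) feed R11p; negative ones (Du*Uxx, kc*V'*U^2 and
    the constant ka*A', sourced off a clamped unit species) feed R11m.
    Squaring yields Error2 = R11^2 at steady state; R11mag carries |R11|.
    """
    missing = {"dUdt", "Uxx", "U", "U2"} - set(taps)
    if missing:
        raise KeyError(f"missing residual taps: {sorted(missing)}")
    crn = CRN("pde_residual")
    crn.clamp("One", 1.0)
    contribs = [
        (taps["dUdt"], 1.0, "R11p"),
        (taps["U"], b.kb * b.B_prime + b.kd, "R11p"),
        (taps["Uxx"], b.Du, "R11m"),
        (taps["U2"], b.kc * b.V_prime, "R11m"),
        ("One", b.ka * b.A_prime, "R11m"),
    ]
    for src, coeff, rail in contribs:
        crn.add_reaction({src: 1}, {src: 1, rail: 1}, coeff * k)
    crn.add_reaction({"R11p": 1}, {}, k)
    crn.add_reaction({"R11m": 1}, {}, k)
    crn.add_reaction({"R11p": 1, "R11m": 1}, {}, gamma)
    crn.merge(build_square_channel(("R11p", "R11m"), "Error2", k))
    # magnitude readout |R11| (surfaced alongside the squared channel)
    crn.add_reaction({"R11p": 1}, {"R11p": 1, "R11mag": 1}, k)
    crn.add_reaction({"R11m": 1}, {"R11m": 1, "R11mag": 1}, k)
    crn.add_reaction({"R11mag": 1}, {}, k)
    return crn


def assemble_loss(
    error1: str = "Error1", error2: str = "Error2", k: float = DEFAULT_K, out: str = "Loss"
) -> CRN:
    """Adder CRN: steady [out] = [error1] + [error2]."""
    return build_adder([error1, error2], out, k)


# ---------------------------------------------------------------------------
# analytic worked example (independent of every CRN path)


def analytic_residual(
    v: VerificationSpec, b: BrusselatorSpec
) -> dict[str, float]:
    """Sympy evaluation of U, its partials, and the reduced-PDE residual."""
    x, t = sympy.symbols("x t")
    U = v.a * x**2 + v.b * t**2 + v.c * x * t
    dUdt = sympy.diff(U, t)
    dUdx = sympy.diff(U, x)
    d2Udx2 = sympy.diff(U, x, 2)
    residual = (
        dUdt
        - b.Du * d2Udx2
        - b.kc * b.V_prime * U**2
        - b.ka * b.A_prime
        + (b.kb * b.B_prime + b.kd) * U
    )
    subs = {x: v.x0, t: v.t0}
    return {
        "U": float(U.subs(subs)),
        "dUdt": float(dUdt.subs(subs)),
        "dUdx": float(dUdx.subs(subs)),
        "d2Udx2": float(d2Udx2.subs(subs)),
        "residual": float(residual.subs(subs)),
    }


def worked_example() -> dict[str, float]:
    """The nominal design point: a=1, b=2, c=0.5 at (x, t) = (0.8, 0.5)."""
    return analytic_residual(VerificationSpec(), BrusselatorSpec())


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineResult:
    trajectory: Trajectory
    steady: dict[str, float]
    converged: bool
    report: ErrorReport
    coefficients: tuple[float, float, float]
    crn: CRN
    channels: dict[str, str] = field(default_factory=dict)


def assemble_full_system(
    v: VerificationSpec | None = None,
    b: BrusselatorSpec | None = None,
    spec: NetworkSpec | None = None,
    *,
    k: float = 3.0e-3,
    k_err: float = 3.0e-3,
    gamma: float = 1.0e3,
    t_end: float = 25000.0,
    train_epochs: int = 20000,
    pretrained_coefficients: tuple[float, float, float] | None = None,
    n_points: int = 500,
) -> PipelineResult:
    """Wire network, partial-derivative, verification, and residual modules.

    The network is trained (reference arithmetic) against the quadratic
    target unless ``pretrained_coefficients`` short-circuits that step; the
    learned quadratic form is compiled chemically, every Table-5 channel is
    built, and the whole mass-action system is integrated at once.
    """
    v = v or VerificationSpec()
    b = b or BrusselatorSpec()
    if pretrained_coefficients is None:
        spec = spec or NetworkSpec()
        target = lambda x, t: v.a * x**2 + v.b * t**2 + v.c * x * t  # noqa: E731
        spec, history = train(spec, target, epochs=train_epochs)
        A, B, C = coefficients(spec)
        log.info("training loss %.3g -> %.3g; coefficients (%.4f, %.4f, %.4f)",
                 history[0], history[-1], A, B, C)
    else:
        A, B, C = pretrained_coefficients

    xv, tv = v.x0, v.t0
    values = {"X": xv, "T": tv}
    crn = CRN("pde_pipeline")
    for var, val in values.items():
        crn.clamp(var, val)

    # learned-function channels (network forward pass, per augmented pattern)
    crn.merge(build_monomial_crn(MonomialTerm.make(A, {"X": 2}), k, "Ux", None))
    crn.merge(build_monomial_crn(MonomialTerm.make(B, {"T": 2}), k, "Ut", None))
    crn.merge(build_monomial_crn(MonomialTerm.make(C, {"X": 1, "T": 1}), k, "Ucombt", None))
    crn.merge(build_adder(["Ux", "Ut", "Ucombt"], "P", k))

    # verification: target function and Error1
    crn.merge(build_target_function_crn(v, k))
    crn.merge(build_error_comparator("P", "Pstar", k_err, gamma, out="Error1"))

    # first-order partials by the division principle
    crn.merge(build_partial_crn("Ux", "X", 2, k, "dUx_dx", values))
    crn.merge(build_partial_crn("Ucombt", "X", 1, k, "dUcombt_dx", values))
    crn.merge(build_adder(["dUx_dx", "dUcombt_dx"], "dUdx", k))
    crn.merge(build_partial_crn("Ut", "T", 2, k, "dUt_dt", values))
    crn.merge(build_partial_crn("Ucombt", "T", 1, k, "dUcombt_dt", values))
    crn.merge(build_adder(["dUt_dt", "dUcombt_dt"], "dUdt", k))

    # second spatial derivative: dUx_dx = 2A x is degree 1 in x, the compound
    # slice dUcombt_dx = C t carries no x and contributes nothing
    crn.merge(build_partial_crn("dUx_dx", "X", 1, k, "Uxx", values))

    # U^2 tap for the nonlinear term
    crn.add_reaction({"P": 2}, {"P": 2, "Usq": 1}, k)
    crn.add_reaction({"Usq": 1}, {}, k)

    crn.merge(
        build_pde_residual_crn(
            b, {"dUdt": "dUdt", "Uxx": "Uxx", "U": "P", "U2": "Usq"}, k_err, gamma
        )
    )
    crn.merge(assemble_loss("Error1", "Error2", k_err))

    traj = simulate(crn, t_end, n_points=n_points)
    channels = [
        "Ux", "Ut", "Ucombt", "P", "Pstar", "Error1",
        "dUx_dx", "dUcombt_dx", "dUdx", "dUt_dt", "dUcombt_dt", "dUdt",
        "Uxx", "Usq", "R11p", "R11m", "R11mag", "Error2", "Loss",
    ]
    steady, converged = steady_state(traj, channels, rel_tol=1e-4)
    report = ErrorReport(
        Error1=steady["Error1"],
        Error2=steady["Error2"],
        Loss=steady["Loss"],
        R11=steady["R11p"] - steady["R11m"],
    )
    return PipelineResult(traj, steady, converged, report, (A, B, C), crn,
                          {name: name for name in channels})
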