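"""Augmented-matrix neural network compiled to CRNs.

The network has N=2 inputs, L=4 hidden units with square activation, a 4x2
linear combination layer and a 2-weight linear readout (dimensions inferred
from the 18-weight nominal inventory).  Because the hidden activation is a
square and later layers are linear, the network output is exactly a quadratic
form  P(x,t) = A x^2 + B t^2 + C x t  whose coefficients follow from the
weights; the augmented identity-matrix input patterns expose each
single-variable slice (A x^2 alone, B t^2 alone) plus the full output, and
the compound contribution C x t is the full-pattern output minus the
single-variable slices.

Training (the error-feedback backward pass) runs as reference arithmetic
that re-parameterizes the weight-adjustment reservoir CRNs; the forward pass
and weight storage are chemical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core import CRN, simulate, steady_state
from .partials import MonomialTerm, build_adder, build_monomial_crn

__all__ = [
    "NetworkSpec",
    "AugmentedMatrix",
    "augment_inputs",
    "coefficients",
    "forward",
    "train",
    "gradient_update",
    "build_weighted_sum_crn",
    "build_square_activation_crn",
    "build_weight_adjustment_crn",
    "weight_equilibrium",
    "run_network",
]

log = logging.getLogger("crnpde")

_TABLE_W_IN = np.array([[0.63, 0.24, 0.06, 0.42], [0.39, 0.36, 0.06, 0.26]])
_TABLE_W_HID = np.array(
    [[0.11, 0.42, 0.09, 0.01], [0.16, 0.06, 0.35, 0.38]]
).T  # 4 hidden units x 2 combination units
_TABLE_W_OUT = np.array([0.19, 0.21])


@dataclass
class NetworkSpec:
    weights_in: np.ndarray = field(default_factory=lambda: _TABLE_W_IN.copy())  # N x L
    weights_hid: np.ndarray = field(default_factory=lambda: _TABLE_W_HID.copy())  # L x M
    weights_out: np.ndarray = field(default_factory=lambda: _TABLE_W_OUT.copy())  # M
    thresholds_hidden: np.ndarray = field(default_factory=lambda: np.zeros(4))
    thresholds_out: np.ndarray = field(default_factory=lambda: np.zeros(2))
    k1: float = 6.0e-5
    k2: float = 6.0e-5
    k3: float = 6.0e-5
    k4: float = 6.0e-5
    k_forward: float = 3.65e-6  # k5, k7, k9, k11, k13
    k_reverse: float = 9.0e-5  # k6, k8, k10, k12, k14
    # learning step: any 0 < alpha < 1 is admissible; 0.05 keeps full-batch
    # descent on the quadratic-form model stable (0.5 overshoots and clips)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.weights_in = np.asarray(self.weights_in, dtype=float)
        self.weights_hid = np.asarray(self.weights_hid, dtype=float)
        self.weights_out = np.asarray(self.weights_out, dtype=float)
        if not 0 < self.alpha < 1:
            raise ValueError("learning step alpha must satisfy 0 < alpha < 1")
        if (self.weights_in < 0).any() or (self.weights_hid < 0).any() or (
            self.weights_out < 0
        ).any():
            raise ValueError("weights must be nonnegative")

    @property
    def n_inputs(self) -> int:
        return self.weights_in.shape[0]


@dataclass(frozen=True)
class AugmentedMatrix:
    """Identity matrix with an appended all-ones row (column selector view)."""

    n: int

    def matrix(self) -> np.ndarray:
        return np.vstack([np.eye(self.n), np.ones(self.n)])

    def patterns(self, x: np.ndarray) -> list[np.ndarray]:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise ValueError(f"input length {x.shape} != N={self.n}")
        return [row * x for row in self.matrix()]


def augment_inputs(x, m: AugmentedMatrix | None = None) -> list[np.ndarray]:
    """N single-variable patterns plus the all-variables pattern."""
    x = np.asarray(x, dtype=float)
    if m is None:
        m = AugmentedMatrix(len(x))
    return m.patterns(x)


# ---------------------------------------------------------------------------
# numeric reference network


def forward(spec: NetworkSpec, x) -> float:
    x = np.asarray(x, dtype=float)
    s1 = x @ spec.weights_in - spec.thresholds_hidden
    y1 = s1**2
    s2 = y1 @ spec.weights_hid - spec.thresholds_out
    return float(s2 @ spec.weights_out)


def coefficients(spec: NetworkSpec) -> tuple[float, float, float]:
    """(A, B, C) of the exact quadratic form P = A x^2 + B t^2 + C x t."""
    v = spec.weights_hid @ spec.weights_out  # effective weight per hidden unit
    wx = spec.weights_in[0]
    wt = spec.weights_in[1]
    a = float(np.sum(v * wx**2))
    b = float(np.sum(v * wt**2))
    c = float(2.0 * np.sum(v * wx * wt))
    return a, b, c


def _grads(spec: NetworkSpec, xs: np.ndarray, targets: np.ndarray):
    s1 = xs @ spec.weights_in  # P x L
    y1 = s1**2
    s2 = y1 @ spec.weights_hid  # P x M
    out = s2 @ spec.weights_out  # P
    err = out - targets
    n = len(xs)
    g_out = (err @ s2) / n
    g_hid = y1.T @ (np.outer(err, spec.weights_out)) / n
    d_y1 = np.outer(err, spec.weights_out) @ spec.weights_hid.T  # P x L
    d_s1 = 2.0 * s1 * d_y1
    g_in = xs.T @ d_s1 / n
    loss = float(0.5 * np.mean(err**2))
    return loss, g_in, g_hid, g_out


def gradient_update(spec: NetworkSpec, grads, alpha: float | None = None) -> NetworkSpec:
    """w(k+1) = w(k) + alpha * delta-w; negative results clip to 0 with a warning."""
    if alpha is None:
        alpha = spec.alpha
    if not 0 < alpha < 1:
        raise ValueError("0 < alpha < 1 required")
    g_in, g_hid, g_out = grads
    new_in = spec.weights_in - alpha * g_in
    new_hid = spec.weights_hid - alpha * g_hid
    new_out = spec.weights_out - alpha * g_out
    clipped = min(new_in.min(), new_hid.min(), new_out.min()) < 0
    if clipped:
        log.warning("weight update drove a weight negative; clipping to 0")
    return replace(
        spec,
        weights_in=np.maximum(new_in, 0.0),
        weights_hid=np.maximum(new_hid, 0.0),
        weights_out=np.maximum(new_out, 0.0),
    )


def train(
    spec: NetworkSpec,
    target_fn,
    epochs: int = 20000,
    alpha: float | None = None,
    grid: int = 5,
    span: tuple[float, float] = (0.1, 1.1),
    seed: int | None = None,
) -> tuple[NetworkSpec, list[float]]:
    """Full-batch gradient descent on 0.5*MSE against ``target_fn(x, t)``.

    Returns the trained spec and the per-epoch loss history.
    """
    if seed is not None:
        rng = np.random.default_rng(seed)
        pts = rng.uniform(span[0], span[1], size=(grid * grid, 2))
    else:
        axis = np.linspace(span[0], span[1], grid)
        pts = np.array([(a, b) for a in axis for b in axis])
    targets = np.array([target_fn(p[0], p[1]) for p in pts])
    history = []
    for _ in range(epochs):
        loss, g_in, g_hid, g_out = _grads(spec, pts, targets)
        history.append(loss)
        spec = gradient_update(spec, (g_in, g_hid, g_out), alpha)
    history.append(_grads(spec, pts, targets)[0])
    return spec, history


# ---------------------------------------------------------------------------
# chemical builders


def build_weighted_sum_crn(
    spec: NetworkSpec,
    x,
    unit: int,
    tag: str = "",
    autocatalytic: bool = False,
) -> CRN:
    """CRN whose steady In realizes the weighted sum of hidden unit ``unit``.

    Default construction: per input a catalytic production Xi + Win ->
    Xi + Win + In at k1 (both clamped), degradation In + Sn -> Sn at k1 with
    Sn clamped at 1, and threshold consumption In + theta_n -> 0 at k1, so
    steady In = sum_i Xi*Win / (1 + theta_n); with theta = 0 this is the
    weighted sum.  ``autocatalytic=True`` emits the literal trimolecular
    variant Xi + Win + In -> Xi + 2 In (structural export only: it has no
    finite nonzero fixed point for In).
    """
    x = np.asarray(x, dtype=float)
    n = unit
    crn = CRN(f"weighted_sum{tag}_u{n}")
    in_name = f"In{n}{tag}"
    s_name = f"Sn{n}{tag}"
    th_name = f"theta{n}{tag}"
    crn.add_species(s_name, initial=1.0, clamped=True)
    theta = float(spec.thresholds_hidden[n])
    for i in range(spec.n_inputs):
        xi = f"X{i}{tag}"
        wi = f"W{i}{n}{tag}"
        crn.clamp(xi, float(x[i]))
        crn.clamp(wi, float(spec.weights_in[i, n]))
        if autocatalytic:
            crn.add_reaction({xi: 1, wi: 1, in_name: 1}, {xi: 1, in_name: 2}, spec.k1)
        else:
            crn.add_reaction({xi: 1, wi: 1}, {xi: 1, wi: 1, in_name: 1}, spec.k1)
    crn.add_reaction({in_name: 1, s_name: 1}, {s_name: 1}, spec.k1)
    if theta > 0:
        crn.clamp(th_name, theta)
        crn.add_reaction({in_name: 1, th_name: 1}, {}, spec.k1)
    return crn


def build_square_activation_crn(input_species: str, output_species: str, k4: float) -> CRN:
    """2I -> 2I + Y at k4 with Y -> 0 at k4: steady Y = I^2."""
    crn = CRN(f"square_{output_species}")
    crn.add_reaction({input_species: 2}, {input_species: 2, output_species: 1}, k4)
    crn.add_reaction({output_species: 1}, {}, k4)
    crn.species[output_species] = type(crn.species[output_species])(
        output_species, "output", False
    )
    return crn


def weight_equilibrium(spec: NetworkSpec, lb: float, la: float) -> float:
    """Closed-form equilibrium of W + La <-> Lb: [W] = (k_rev/k_fwd) * Lb/La."""
    return (spec.k_reverse / spec.k_forward) * lb / la


def build_weight_adjustment_crn(
    spec: NetworkSpec,
    weights: dict[str, float],
    reservoir: float = 1000.0,
    tag: str = "",
) -> CRN:
    """Reversible buffering reactions storing each weight value.

    Per weight W:  W + La <->(k5, k6) Lb with reservoirs chosen so the
    equilibrium [W] equals the requested value; Lb is initialized at
    ``reservoir`` (>> [W], the Eq-10-style condition) and La at
    (k6/k5) * Lb / w.
    """
    crn = CRN(f"weight_adjustment{tag}")
    for name, w in weights.items():
        if w <= 0:
            raise ValueError(f"weight {name} must be positive to back-solve reservoirs")
        lb0 = reservoir
        la0 = (spec.k_reverse / spec.k_forward) * lb0 / w
        if lb0 / max(w, 1e-12) < 10:
            log.warning("reservoir ratio < 10 for %s; buffering condition violated", name)
        crn.add_species(f"{name}{tag}", initial=0.0)
        crn.add_species(f"La_{name}{tag}", initial=la0)
        crn.add_species(f"Lb_{name}{tag}", initial=lb0)
        crn.add_reaction(
            {f"{name}{tag}": 1, f"La_{name}{tag}": 1},
            {f"Lb_{name}{tag}": 1},
            spec.k_forward,
            reverse_rate=spec.k_reverse,
        )
    return crn


# ---------------------------------------------------------------------------
# full forward pass


@dataclass
class NetworkRunResult:
    outputs: dict[str, float]  # per-pattern chemical steady outputs
    reference: dict[str, float]  # numeric oracle per pattern
    error1: float
    converged: bool
    coefficients: tuple[float, float, float]
    crn: CRN | None = None


def run_network(
    spec: NetworkSpec,
    x,
    target_fn=None,
    k: float = 6.0e-4,
    t_end: float = 25000.0,
    chemical: bool = True,
) -> NetworkRunResult:
    """Simulate the compiled forward cascade for every augmented pattern.

    The learned quadratic form (A, B, C) is compiled to monomial CRNs: the
    x-only pattern yields the single-variable accumulation Ux = A x^2, the
    t-only pattern Ut = B t^2, and the all-ones pattern the full output P
    with the compound channel Ucombt = C x t.  Error1 compares P with the
    target value when ``target_fn`` is given.
    """
    x = np.asarray(x, dtype=float)
    a, b, c = coefficients(spec)
    xv, tv = float(x[0]), float(x[1])
    reference = {
        "Ux": a * xv**2,
        "Ut": b * tv**2,
        "Ucombt": c * xv * tv,
        "P": forward(spec, x),
    }
    if not chemical:
        pstar = target_fn(xv, tv) if target_fn else reference["P"]
        return NetworkRunResult(
            dict(reference), reference, abs(reference["P"] - pstar), True, (a, b, c)
        )

    crn = CRN("ann_forward")
    values = {"X": xv, "T": tv}
    crn.merge(build_monomial_crn(MonomialTerm.make(a, {"X": 2}), k, "Ux", values))
    crn.merge(build_monomial_crn(MonomialTerm.make(b, {"T": 2}), k, "Ut", values))
    crn.merge(build_monomial_crn(MonomialTerm.make(c, {"X": 1, "T": 1}), k, "Ucombt", values))
    crn.merge(build_adder(["Ux", "Ut", "Ucombt"], "P", k))
    traj = simulate(crn, t_end)
    vals, converged = steady_state(traj, ["Ux", "Ut", "Ucombt", "P"], rel_tol=1e-4)
    pstar = target_fn(xv, tv) if target_fn else reference["P"]
    if not converged:
        log.warning("ann forward cascade not converged by t=%g s", t_end)
    return NetworkRunResult(
        vals, reference, abs(vals["P"] - pstar), converged, (a, b, c), crn
    )

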