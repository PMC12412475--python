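"""Core chemical reaction network (CRN) data model and mass-action simulation.

Concentrations are in nM and time in seconds throughout.  Rate constants are
stored in s^-1 * nM^(1-order) where ``order`` is the total reactant
multiplicity of the reaction; :func:`per_molar` converts literature rates
quoted in /M/s.

A CRN is a set of named species, a list of (possibly reversible) mass-action
reactions, initial concentrations, and optionally *drives*: species whose
concentration is an explicit function of time (used to feed analytic test
signals into a module without building the upstream network).  Clamped
species are held at their initial concentration during integration.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Species",
    "Reaction",
    "CRN",
    "Trajectory",
    "DualRailSignal",
    "CRNError",
    "IntegrationError",
    "per_molar",
    "mass_action_odes",
    "stoichiometry_matrix",
    "simulate",
    "steady_state",
    "dual_rail_encode",
    "dual_rail_read",
]

log = logging.getLogger("crnpde")

#: species roles
ROLES = ("input", "output", "auxiliary", "intermediate", "waste", "internal")

#: negative excursions smaller than this (nM) are clipped to zero
TOL_NEG = 1e-9


class CRNError(ValueError):
    """Structural error in a CRN definition."""


class IntegrationError(RuntimeError):
    """Stiff-solver failure or unacceptable negative excursion."""


def per_molar(k: float) -> float:
    """Convert a bimolecular rate in /M/s to /nM/s (1 /M/s = 1e-9 /nM/s)."""
    return k * 1e-9


@dataclass(frozen=True)
class Species:
    name: str
    role: str = "internal"
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise CRNError(f"unknown species role {self.role!r}")


class Reaction:
    """A mass-action reaction with optional reverse rate.

    ``reactants`` and ``products`` are multisets (mappings name -> multiplicity).
    """

    __slots__ = ("reactants", "products", "rate", "reverse_rate")

    def __init__(
        self,
        reactants: Mapping[str, int] | Iterable[str],
        products: Mapping[str, int] | Iterable[str],
        rate: float,
        reverse_rate: float | None = None,
    ) -> None:
        self.reactants = Counter(reactants)
        self.products = Counter(products)
        self.rate = float(rate)
        self.reverse_rate = None if reverse_rate is None else float(reverse_rate)
        if self.rate < 0:
            raise CRNError(f"negative rate {self.rate}")
        if self.reverse_rate is not None and self.reverse_rate < 0:
            raise CRNError(f"negative reverse rate {self.reverse_rate}")
        if self.order > 3:
            raise CRNError(f"reaction order {self.order} > 3 not supported: {self}")

    @property
    def order(self) -> int:
        return sum(self.reactants.values())

    @property
    def reversible(self) -> bool:
        return self.reverse_rate is not None

    def net(self, name: str) -> int:
        return self.products.get(name, 0) - self.reactants.get(name, 0)

    def species_names(self) -> set[str]:
        return set(self.reactants) | set(self.products)

    def reversed(self) -> "Reaction":
        return Reaction(self.products, self.reactants, self.reverse_rate or 0.0)

    def _side(self, c: Counter) -> str:
        if not c:
            return "0"
        parts = []
        for name in sorted(c):
            m = c[name]
            parts.append(name if m == 1 else f"{m} {name}")
        return " + ".join(parts)

    def __repr__(self) -> str:
        arrow = "<->" if self.reversible else "->"
        rate = f"{self.rate:g}"
        if self.reversible:
            rate += f",{self.reverse_rate:g}"
        return f"{self._side(self.reactants)} {arrow} {self._side(self.products)} @ {rate}"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Reaction):
            return NotImplemented
        return (
            self.reactants == other.reactants
            and self.products == other.products
            and self.rate == other.rate
            and self.reverse_rate == other.reverse_rate
        )


class CRN:
    """Species + reactions + initial concentrations."""

    def __init__(self, name: str = "crn") -> None:
        self.name = name
        self.species: dict[str, Species] = {}
        self.reactions: list[Reaction] = []
        self.initial: dict[str, float] = {}
        self.drives: dict[str, Callable[[float], float]] = {}

    # -- construction -----------------------------------------------------
    def add_species(
        self,
        name: str,
        initial: float = 0.0,
        role: str = "internal",
        clamped: bool = False,
    ) -> Species:
        if name in self.species:
            sp = self.species[name]
            if clamped and not sp.clamped:
                sp = Species(name, sp.role, True)
                self.species[name] = sp
            if initial:
                self.initial[name] = float(initial)
            return sp
        if initial < 0:
            raise CRNError(f"negative initial concentration for {name}")
        sp = Species(name, role, clamped)
        self.species[name] = sp
        self.initial[name] = float(initial)
        return sp

    def add_reaction(
        self,
        reactants: Mapping[str, int] | Iterable[str],
        products: Mapping[str, int] | Iterable[str],
        rate: float,
        reverse_rate: float | None = None,
        declare: bool = True,
    ) -> Reaction:
        rxn = Reaction(reactants, products, rate, reverse_rate)
        for name in [*rxn.reactants, *rxn.products]:  # deterministic order
            if name not in self.species:
                if not declare:
                    raise CRNError(f"reaction references undeclared species {name!r}")
                self.add_species(name)
        self.reactions.append(rxn)
        return rxn

    def set_drive(self, name: str, fn: Callable[[float], float]) -> None:
        """Drive a species concentration as an explicit function of time."""
        if name not in self.species:
            self.add_species(name)
        self.drives[name] = fn

    def clamp(self, name: str, value: float) -> None:
        self.add_species(name, initial=value, clamped=True)
        self.initial[name] = float(value)

    def merge(self, other: "CRN") -> "CRN":
        """In-place union of species/reactions; duplicate reactions sum rates."""
        for name, sp in other.species.items():
            self.add_species(name, other.initial.get(name, 0.0), sp.role, sp.clamped)
        for rxn in other.reactions:
            dup = next(
                (
                    r
                    for r in self.reactions
                    if r.reactants == rxn.reactants
                    and r.products == rxn.products
                    and (r.reverse_rate is None) == (rxn.reverse_rate is None)
                ),
                None,
            )
            if dup is not None:
                dup.rate += rxn.rate
                if rxn.reverse_rate is not None:
                    dup.reverse_rate = (dup.reverse_rate or 0.0) + rxn.reverse_rate
            else:
                self.add_reaction(rxn.reactants, rxn.products, rxn.rate, rxn.reverse_rate)
        self.drives.update(other.drives)
        return self

    # -- views ------------------------------------------------------------
    def species_order(self) -> list[str]:
        return list(self.species)

    def validate(self) -> None:
        for rxn in self.reactions:
            for name in rxn.species_names():
                if name not in self.species:
                    raise CRNError(f"reaction references undeclared species {name!r}")
        for name, v in self.initial.items():
            if v < 0:
                raise CRNError(f"negative initial concentration for {name}")

    def __repr__(self) -> str:
        return f"<CRN {self.name}: {len(self.species)} species, {len(self.reactions)} reactions>"


# ---------------------------------------------------------------------------
# mass-action kinetics


def _elementary(crn: CRN) -> list[Reaction]:
    """Expand reversible reactions into irreversible pairs."""
    out: list[Reaction] = []
    for rxn in crn.reactions:
        out.append(Reaction(rxn.reactants, rxn.products, rxn.rate))
        if rxn.reversible:
            out.append(rxn.reversed())
    return out


def stoichiometry_matrix(crn: CRN) -> np.ndarray:
    """Integer net-stoichiometry matrix, species x elementary reactions."""
    crn.validate()
    order = crn.species_order()
    idx = {n: i for i, n in enumerate(order)}
    rxns = _elementary(crn)
    mat = np.zeros((len(order), len(rxns)), dtype=int)
    for j, rxn in enumerate(rxns):
        for name in rxn.species_names():
            mat[idx[name], j] = rxn.net(name)
    return mat


def rate_laws(crn: CRN, y: np.ndarray, t: float = 0.0) -> np.ndarray:
    """Mass-action flux of each elementary reaction at state ``y``."""
    order = crn.species_order()
    idx = {n: i for i, n in enumerate(order)}
    conc = y.copy()
    for name, fn in crn.drives.items():
        conc[idx[name]] = fn(t)
    fluxes = []
    for rxn in _elementary(crn):
        v = rxn.rate
        for name, m in rxn.reactants.items():
            v *= conc[idx[name]] ** m
        fluxes.append(v)
    return np.asarray(fluxes)


def mass_action_odes(crn: CRN):
    """Return ``(f, order)``: RHS function f(t, y) and the species ordering.

    ``d[s]/dt = sum_r net_r(s) * rate_r * prod [reactant]^mult``; clamped and
    driven species get derivative 0.
    """
    crn.validate()
    order = crn.species_order()
    idx = {n: i for i, n in enumerate(order)}
    frozen = np.array(
        [crn.species[n].clamped or n in crn.drives for n in order], dtype=bool
    )
    rxns = _elementary(crn)
    # precompute index/multiplicity arrays per reaction
    compiled = []
    for rxn in rxns:
        r_idx = np.array([idx[n] for n in rxn.reactants], dtype=int)
        r_mul = np.array([rxn.reactants[n] for n in rxn.reactants], dtype=float)
        touched = sorted(rxn.species_names())
        n_idx = np.array([idx[n] for n in touched], dtype=int)
        n_net = np.array([rxn.net(n) for n in touched], dtype=float)
        compiled.append((rxn.rate, r_idx, r_mul, n_idx, n_net))
    drives = [(idx[n], fn) for n, fn in crn.drives.items()]

    def f(t: float, y: np.ndarray) -> np.ndarray:
        conc = np.maximum(y, 0.0)
        for i, fn in drives:
            conc[i] = fn(t)
        dy = np.zeros_like(y)
        for rate, r_idx, r_mul, n_idx, n_net in compiled:
            if rate == 0.0:
                continue
            flux = rate * np.prod(conc[r_idx] ** r_mul)
            dy[n_idx] += n_net * flux
        dy[frozen] = 0.0
        return dy

    return f, order


def symbolic_odes(crn: CRN):
    """Sympy RHS expressions per species (used by consistency property tests)."""
    import sympy as sp

    order = crn.species_order()
    syms = {n: sp.Symbol(n, nonnegative=True) for n in order}
    exprs = {n: sp.Integer(0) for n in order}
    for rxn in _elementary(crn):
        flux = sp.Float(rxn.rate)
        for name, m in rxn.reactants.items():
            flux *= syms[name] ** m
        for name in rxn.species_names():
            exprs[name] += rxn.net(name) * flux
    for n in order:
        if crn.species[n].clamped or n in crn.drives:
            exprs[n] = sp.Integer(0)
    return exprs, syms


# ---------------------------------------------------------------------------
# integration


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_species)
    species: list[str]
    steady_state_reached: bool = False
    steady_state_time: float | None = None
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.species)}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self._index[name]]

    def final(self, name: str) -> float:
        return float(self.states[-1, self._index[name]])

    def final_state(self) -> dict[str, float]:
        return {n: float(self.states[-1, i]) for n, i in self._index.items()}

    def value_at(self, name: str, t: float) -> float:
        return float(np.interp(t, self.times, self[name]))

    def to_csv(self, path) -> None:
        """CSV export, header ``time,<species...>``; time s, concentrations nM."""
        import pandas as pd

        df = pd.DataFrame(self.states, columns=self.species)
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)


def simulate(
    crn: CRN,
    t_end: float,
    *,
    t_eval: Sequence[float] | None = None,
    n_points: int = 400,
    method: str = "BDF",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    check_steady: bool = True,
    rel_tol: float = 1e-6,
    max_step: float | None = None,
) -> Trajectory:
    """Integrate the mass-action ODEs to ``t_end`` with a stiff solver.

    Clamped/driven species are held; concentrations are clipped to zero when
    the excursion is within ``TOL_NEG`` of zero (larger excursions abort).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    f, order = mass_action_odes(crn)
    y0 = np.array([crn.initial.get(n, 0.0) for n in order], dtype=float)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, n_points)
    else:
        t_eval = np.asarray(t_eval, dtype=float)
    kwargs = {}
    if max_step is not None:
        kwargs["max_step"] = max_step
    sol = solve_ivp(
        f, (0.0, float(t_end)), y0, method=method, t_eval=t_eval, rtol=rtol, atol=atol, **kwargs
    )
    if not sol.success:
        raise IntegrationError(f"stiff solver failed on {crn.name}: {sol.message}")
    states = sol.y.T.copy()
    # driven species: record the driven value, not the integrated dummy
    idx = {n: i for i, n in enumerate(order)}
    for name, fn in crn.drives.items():
        states[:, idx[name]] = [fn(t) for t in sol.t]
    worst = states.min()
    # solver tolerance can leave excursions slightly beyond TOL_NEG on stiff
    # annihilation systems; abort only well beyond the atol scale
    if worst < -max(TOL_NEG, 100 * atol, 1e-6 * max(1.0, states.max())):
        raise IntegrationError(f"negative excursion {worst:g} nM in {crn.name}")
    if worst < 0:
        log.debug("clipping negative excursion %g nM in %s", worst, crn.name)
        states = np.maximum(states, 0.0)
    traj = Trajectory(sol.t, states, order)
    if check_steady:
        _flag_steady(traj, rel_tol=rel_tol)
    return traj


#: absolute convergence floor (nM): changes below this count as settled
ABS_SETTLE = 1e-6


def _flag_steady(traj: Trajectory, rel_tol: float = 1e-6, window_frac: float = 0.05) -> None:
    t_end = traj.times[-1]
    window = window_frac * t_end
    mask = traj.times >= t_end - window
    if mask.sum() < 2:
        return
    seg = traj.states[mask]
    scale = np.abs(seg).max(axis=0)
    change = seg.max(axis=0) - seg.min(axis=0)
    ok = (change <= ABS_SETTLE) | (change <= rel_tol * np.maximum(scale, 1e-12))
    if ok.all():
        traj.steady_state_reached = True
        traj.steady_state_time = float(traj.times[mask][0])


def steady_state(
    traj: Trajectory,
    species_subset: Sequence[str] | None = None,
    rel_tol: float = 1e-6,
    window: float | None = None,
) -> tuple[dict[str, float], bool]:
    """Trailing-window mean per species and a converged flag.

    Not-converged when the max relative change of any requested species over
    the window exceeds ``rel_tol``.
    """
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    t_end = traj.times[-1]
    if window is None:
        window = 0.05 * t_end
    if window > t_end:
        raise ValueError("window longer than trajectory")
    names = list(species_subset) if species_subset is not None else list(traj.species)
    mask = traj.times >= t_end - window
    converged = True
    out = {}
    for n in names:
        seg = traj[n][mask]
        out[n] = float(seg.mean())
        change = seg.max() - seg.min()
        if change > ABS_SETTLE and change > rel_tol * max(abs(seg).max(), 1e-12):
            converged = False
    return out, converged


# ---------------------------------------------------------------------------
# dual-rail encoding


@dataclass(frozen=True)
class DualRailSignal:
    """A signed quantity carried by a (plus, minus) species pair."""

    plus: str
    minus: str


def add_dual_rail(crn: CRN, plus: str, minus: str, annihilation_rate: float) -> DualRailSignal:
    crn.add_species(plus)
    crn.add_species(minus)
    crn.add_reaction({plus: 1, minus: 1}, {}, annihilation_rate)
    return DualRailSignal(plus, minus)


def _has_annihilation(crn: CRN, pair: DualRailSignal) -> bool:
    target = Counter({pair.plus: 1, pair.minus: 1})
    return any(r.reactants == target and not r.products for r in crn.reactions)


def dual_rail_encode(crn: CRN, value: float, pair: DualRailSignal) -> dict[str, float]:
    """Set initial concentrations encoding ``value`` on the pair canonically."""
    if not _has_annihilation(crn, pair):
        log.warning("dual-rail pair (%s, %s) lacks an annihilation reaction", pair.plus, pair.minus)
    enc = {pair.plus: max(value, 0.0), pair.minus: max(-value, 0.0)}
    crn.initial.update(enc)
    return enc


def dual_rail_read(state: Mapping[str, float], pair: DualRailSignal) -> float:
    return float(state[pair.plus] - state[pair.minus])


def closed_form_decay(a0: float, gamma: float, t: np.ndarray) -> np.ndarray:
    """Analytic solution of A -> 0 at rate gamma (test oracle)."""
    return a0 * np.exp(-gamma * np.asarray(t))
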