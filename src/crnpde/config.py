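"""Pipeline configuration: the nominal rate/weight tables, verbatim keys.

The YAML round-trips exactly through :func:`load_config` / :func:`dump_config`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .ann import NetworkSpec
from .brusselator import BrusselatorSpec, VerificationSpec
from .differentiator import DifferentiatorConfig

__all__ = ["PipelineConfig", "load_config", "dump_config"]


def _table2() -> dict:
    return {
        "k1": 6.0e-5, "k2": 6.0e-5, "k3": 6.0e-5, "k4": 6.0e-5,
        "k5": 3.65e-6, "k7": 3.65e-6, "k9": 3.65e-6, "k11": 3.65e-6, "k13": 3.65e-6,
        "k6": 9.0e-5, "k8": 9.0e-5, "k10": 9.0e-5, "k12": 9.0e-5, "k14": 9.0e-5,
        "W11": 0.63, "W12": 0.24, "W13": 0.06, "W14": 0.42,
        "W21": 0.39, "W22": 0.36, "W23": 0.06, "W24": 0.26,
        "W31": 0.11, "W32": 0.42, "W33": 0.09, "W34": 0.01,
        "W41": 0.16, "W42": 0.06, "W43": 0.35, "W44": 0.38,
        "W51": 0.19, "W52": 0.21,
    }


def _table3() -> dict:
    return {
        "k_diff": 4.0e-4, "k": 3.0e-3, "k_fast": 10.0,
        "alpha_a": 5.0e-4, "beta_a": 5.0e-4, "delta_a": 5.0e-4,
        "gamma_a": 1.0, "k_x": 6.0e-4,
    }


def _table4() -> dict:
    return {
        "D_u": 0.5, "k_a": 1.0, "k_b": 0.3, "k_c": 0.2, "k_d": 0.1,
        "A_prime": 2.0, "B_prime": 2.0, "V_prime": 1.0,
    }


@dataclass
class PipelineConfig:
    table2: dict = field(default_factory=_table2)
    table3: dict = field(default_factory=_table3)
    table4: dict = field(default_factory=_table4)
    x0: float = 0.8
    t0: float = 0.5
    a: float = 1.0
    b: float = 2.0
    c: float = 0.5
    t_end: float = 25000.0
    check_horizon: float = 12500.0
    rel_tol: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for table in (self.table2, self.table3, self.table4):
            for key, val in table.items():
                if key.startswith(("k", "alpha", "beta", "delta", "gamma", "D")) and val <= 0:
                    raise ValueError(f"rate {key} must be > 0")

    # -- views into module specs ------------------------------------------
    def network_spec(self) -> NetworkSpec:
        t2 = self.table2
        w_in = np.array(
            [[t2["W11"], t2["W12"], t2["W13"], t2["W14"]],
             [t2["W21"], t2["W22"], t2["W23"], t2["W24"]]]
        )
        w_hid = np.array(
            [[t2["W31"], t2["W32"], t2["W33"], t2["W34"]],
             [t2["W41"], t2["W42"], t2["W43"], t2["W44"]]]
        ).T
        w_out = np.array([t2["W51"], t2["W52"]])
        return NetworkSpec(
            weights_in=w_in, weights_hid=w_hid, weights_out=w_out,
            k1=t2["k1"], k2=t2["k2"], k3=t2["k3"], k4=t2["k4"],
            k_forward=t2["k5"], k_reverse=t2["k6"],
        )

    def differentiator_config(self) -> DifferentiatorConfig:
        t3 = self.table3
        return DifferentiatorConfig(
            kdiff=t3["k_diff"], k=t3["k"], kfast=t3["k_fast"],
            alpha_a=t3["alpha_a"], beta_a=t3["beta_a"], delta_a=t3["delta_a"],
            gamma_a=t3["gamma_a"],
        )

    def brusselator_spec(self) -> BrusselatorSpec:
        t4 = self.table4
        return BrusselatorSpec(
            ka=t4["k_a"], kb=t4["k_b"], kc=t4["k_c"], kd=t4["k_d"],
            Du=t4["D_u"], A_prime=t4["A_prime"], B_prime=t4["B_prime"],
            V_prime=t4["V_prime"],
        )

    def verification_spec(self) -> VerificationSpec:
        return VerificationSpec(a=self.a, b=self.b, c=self.c, x0=self.x0, t0=self.t0)


def dump_config(cfg: PipelineConfig) -> str:
    return yaml.safe_dump(asdict(cfg), sort_keys=True)


def load_config(text: str) -> PipelineConfig:
    data = yaml.safe_load(text)
    return PipelineConfig(**data)
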