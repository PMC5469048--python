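"""Hyperparameter optimization for the doppelganger learners.

Each learner's hyperparameters are tuned to minimize its mean unsigned error
on shot 15, the end of the block, under the full task distribution (random
mappings and targets) at the subject's matched initial policy and response
variability.  The stochastic objective is made quasi-deterministic with
common random numbers — one fixed set of mappings, targets, and standard
normal noise draws shared by all evaluations — and minimized with
Nelder-Mead in transformed coordinates (log for rates and sigma_g, logit for
the RLS forgetting factor mu), with multiple starts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .learners import FirstConfig, SecondConfig, ZerothConfig, simulate_blocks
from .task import B_STAR_RANGE, ExperimentDesign, TARGET_BOUND, W_STAR_RANGE

__all__ = [
    "HyperparamSpec",
    "ShotErrorObjective",
    "optimize_hyperparams",
    "grid_search",
    "HyperoptResult",
]

#: Search boxes.  Rates and sigma_g are searched in log space, mu in logit space.
#: The LMS rates are capped at 2: |1 - eta*j^2| <= 1 for the physical joystick
#: range |j| <= 1, so every admissible rate is stable on every block.
_BOUNDS = {
    "zeroth": {"sigma_g": (1e-4, 1.0), "eta": (1e-2, 1e4)},
    "zeroth3": {"sigma_g": (1e-4, 1.0), "eta_w": (1e-2, 1e4), "eta_b": (1e-2, 1e4)},
    "first": {"eta_m": (1e-4, 2.0), "eta_s": (1e-4, 2.0)},
    "second": {"mu": (1e-6, 1.0)},
}

_DEFAULT_START = {
    "zeroth": {"sigma_g": 0.05, "eta": 1.0},
    "zeroth3": {"sigma_g": 0.05, "eta_w": 1.0, "eta_b": 1.0},
    "first": {"eta_m": 0.1, "eta_s": 0.1},
    "second": {"mu": 0.9},
}


@dataclass(frozen=True)
class HyperparamSpec:
    """Names, bounds, and transforms for one learner order's hyperparameters."""

    order: str
    names: tuple
    bounds: dict

    @classmethod
    def for_order(cls, order: str) -> "HyperparamSpec":
        if order not in _BOUNDS:
            raise ValueError(f"unknown learner order {order!r}")
        b = _BOUNDS[order]
        return cls(order=order, names=tuple(b), bounds=dict(b))

    def default_start(self) -> dict:
        return dict(_DEFAULT_START[self.order])

    def validate(self, params: dict) -> None:
        for name in self.names:
            lo, hi = self.bounds[name]
            v = params[name]
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside bounds ({lo}, {hi})")

    # -- transforms ----------------------------------------------------------

    def to_vector(self, params: dict) -> np.ndarray:
        out = []
        for name in self.names:
            v = params[name]
            if name == "mu":
                out.append(logit(np.clip(v, 1e-9, 1 - 1e-9)))
            else:
                out.append(np.log(v))
        return np.array(out)

    def from_vector(self, vec: np.ndarray) -> dict:
        params = {}
        for name, v in zip(self.names, vec):
            if name == "mu":
                params[name] = float(expit(v))
            else:
                lo, hi = self.bounds[name]
                params[name] = float(np.clip(np.exp(v), lo, hi))
        return params

    def make_config(self, params: dict, sigma_r: float = 0.0):
        if self.order == "zeroth":
            return ZerothConfig(sigma_g=params["sigma_g"], eta=params["eta"])
        if self.order == "zeroth3":
            return ZerothConfig(
                sigma_g=params["sigma_g"], eta=params["eta_w"], eta_b=params["eta_b"]
            )
        if self.order == "first":
            return FirstConfig(eta_m=params["eta_m"], eta_s=params["eta_s"], sigma_r=sigma_r)
        return SecondConfig(mu=params["mu"], sigma_r=sigma_r)

    def sample(self, rng: np.random.Generator) -> dict:
        """Random in-bounds draw (log-uniform; logit-uniform for mu)."""
        params = {}
        for name in self.names:
            lo, hi = self.bounds[name]
            if name == "mu":
                params[name] = float(expit(rng.uniform(logit(0.02), logit(0.995))))
            else:
                params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return params


class ShotErrorObjective:
    """Mean shot-15 unsigned error as a function of the hyperparameters.

    The Monte-Carlo sample — ``mc_blocks`` random blocks with their targets
    and the standard-normal noise stream — is drawn once at construction and
    reused for every evaluation (common random numbers), so repeated calls at
    the same hyperparameters return the identical value.  Pass ``design`` to
    evaluate on a subject's fixed 24-block design instead of fresh task draws.
    """

    def __init__(
        self,
        spec: HyperparamSpec,
        w0: float,
        b0: float,
        rng: np.random.Generator,
        sigma_r: float = 0.0,
        mc_blocks: int = 2000,
        n_shots: int = 15,
        design: ExperimentDesign = None,
    ):
        self.spec = spec
        self.w0, self.b0 = w0, b0
        self.sigma_r = sigma_r
        if design is not None:
            m, s, x = design.test_arrays()
            reps = max(1, int(np.ceil(mc_blocks / len(m))))
            self.m = np.tile(m, reps)
            self.s = np.tile(s, reps)
            self.targets = np.tile(x, (reps, 1))
        else:
            w_star = rng.uniform(*W_STAR_RANGE, size=mc_blocks)
            b_star = rng.uniform(*B_STAR_RANGE, size=mc_blocks)
            self.m = 1.0 / w_star
            self.s = -b_star / w_star
            self.targets = rng.uniform(-TARGET_BOUND, TARGET_BOUND, size=(mc_blocks, n_shots))
        self.z = rng.standard_normal(self.targets.shape)
        self.n_evals = 0

    def __call__(self, params: dict) -> float:
        self.spec.validate(params)
        config = self.spec.make_config(params, sigma_r=self.sigma_r)
        err = simulate_blocks(config, self.w0, self.b0, self.m, self.s, self.targets, self.z)
        self.n_evals += 1
        return float(err[:, -1].mean())


@dataclass
class HyperoptResult:
    params: dict
    objective: float
    n_evals: int
    converged: bool
    starts: list = field(default_factory=list)  # (start params, best objective) per start


def optimize_hyperparams(
    spec: HyperparamSpec,
    objective: ShotErrorObjective,
    rng: np.random.Generator,
    n_starts: int = 5,
    maxiter: int = 400,
) -> HyperoptResult:
    """Multi-start Nelder-Mead over the transformed hyperparameter space."""
    starts = [spec.default_start()] + [spec.sample(rng) for _ in range(n_starts - 1)]
    best = None
    trace = []
    any_converged = False
    for start in starts:
        x0 = spec.to_vector(start)
        res = minimize(
            lambda v: objective(spec.from_vector(v)),
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-8},
        )
        any_converged = any_converged or bool(res.success)
        trace.append((start, float(res.fun)))
        if best is None or res.fun < best[1]:
            best = (spec.from_vector(res.x), float(res.fun))
    params, value = best
    spec.validate(params)
    return HyperoptResult(
        params=params,
        objective=value,
        n_evals=objective.n_evals,
        converged=any_converged,
        starts=trace,
    )


def grid_search(spec: HyperparamSpec, objective, n_points: int = 11):
    """Brute-force log/logit grid over the bounds; returns (best params, best value)."""
    axes = []
    for name in spec.names:
        lo, hi = spec.bounds[name]
        if name == "mu":
            axes.append(expit(np.linspace(logit(0.02), logit(0.995), n_points)))
        else:
            axes.append(np.exp(np.linspace(np.log(lo), np.log(hi), n_points)))
    best = None
    mesh = np.meshgrid(*axes, indexing="ij")
    for idx in np.ndindex(*mesh[0].shape):
        params = {name: float(ax[i]) for name, ax, i in zip(spec.names, axes, idx)}
        v = objective(params)
        if best is None or v < best[1]:
            best = (params, v)
    return best
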