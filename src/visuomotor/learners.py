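"""The three doppelganger learning algorithms: node perturbation, LMS, RLS.

Every learner uses the linear policy ``j = w*x + b`` plus a Gaussian noise term
and adjusts (w, b) from shooting feedback, clipping them to the known
hypothesis-space box w in [0.25, 1.75], b in [-0.25, 0.25] after every update.

* zeroth order (node perturbation): the noise ``g`` is the learning signal.
  After each shot, ``w <- w - eta*(L - L_prev)*g*x`` and
  ``b <- b - eta*(L - L_prev)*g`` with loss L = e^2.  Shot 1 performs no
  update (L_prev is seeded with the first loss).
* first order (LMS): learns the mapping estimates by stochastic gradient
  descent on the forward-model prediction error.  Because the learner aims
  its shot so that the predicted cursor lands on the target
  (m_est*j + s_est = x), the shooting error e = c - x *is* the prediction
  error of the model c = m_est*j + s_est, and the LMS step is
  ``m_est <- m_est + eta_m*e*j`` and ``s_est <- s_est + eta_s*e`` (the same
  +e innovation the RLS rule uses; equivalently the classical "minus" form
  with the error written as x - c).  The policy follows as w = 1/m_est,
  b = -s_est/m_est.  A response-noise term ``r`` with SD sigma_r models
  human motor variability.
* second order (RLS): gain matrix P (initialized to I) with forgetting
  hyperparameter mu: y = (j, 1)^T, v = P y, k = v^T/(mu + y^T v), P <- P - v k,
  m_est <- m_est + e*k1, s_est <- s_est + e*k2.  The P update is used exactly
  in that form; set ``textbook_update=True`` for the conventional variant that
  additionally rescales P by 1/mu.

Two implementations are provided on purpose: scalar per-shot operations
(`act`, `update`, `run_block`) that transcribe the rules one shot at a time,
and a vectorized engine (`simulate_blocks`, `run_experiment`) that runs many
blocks in parallel for Monte-Carlo work.  They are tested against each other.

Joystick positions are *not* clipped to [-1, 1] inside simulations: the
mapping and target ranges guarantee the optimal action is in range, and rare
noise excursions beyond are treated as linear extrapolation rather than
introducing an unmodeled saturation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

from .task import B_STAR_RANGE, Block, ExperimentDesign, Mapping, W_STAR_RANGE

__all__ = [
    "ZerothConfig",
    "FirstConfig",
    "SecondConfig",
    "ZerothState",
    "FirstState",
    "SecondState",
    "ShotRecord",
    "DegenerateEstimateError",
    "init_state",
    "act",
    "update",
    "update_zeroth",
    "update_first",
    "update_second",
    "run_block",
    "simulate_blocks",
    "run_experiment",
    "run_long_block",
    "curves_to_csv",
]

W_LO, W_HI = W_STAR_RANGE
B_LO, B_HI = B_STAR_RANGE


class DegenerateEstimateError(ArithmeticError):
    """Raised when a mapping estimate collapses (m_est == 0 or RLS denominator <= 0)."""


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZerothConfig:
    """Node-perturbation hyperparameters.

    ``eta_b`` enables the three-hyperparameter variant with separate learning
    rates for w and b; by default both use ``eta``.
    """

    sigma_g: float
    eta: float
    eta_b: float = None  # type: ignore[assignment]

    order = "zeroth"

    def __post_init__(self):
        # zero values are permitted for no-noise / no-learning diagnostics
        if self.sigma_g < 0 or self.eta < 0:
            raise ValueError("sigma_g and eta must be non-negative")

    @property
    def eta_w(self) -> float:
        return self.eta

    @property
    def eta_bias(self) -> float:
        return self.eta if self.eta_b is None else self.eta_b

    @property
    def sigma(self) -> float:
        return self.sigma_g


@dataclass(frozen=True)
class FirstConfig:
    """LMS hyperparameters plus matched response variability."""

    eta_m: float
    eta_s: float
    sigma_r: float = 0.0

    order = "first"

    def __post_init__(self):
        if self.eta_m < 0 or self.eta_s < 0 or self.sigma_r < 0:
            raise ValueError("rates and sigma_r must be non-negative")

    @property
    def sigma(self) -> float:
        return self.sigma_r


@dataclass(frozen=True)
class SecondConfig:
    """RLS forgetting hyperparameter plus matched response variability."""

    mu: float
    sigma_r: float = 0.0
    textbook_update: bool = False

    order = "second"

    def __post_init__(self):
        if not (0.0 < self.mu <= 1.0):
            raise ValueError("mu must be in (0, 1]")
        if self.sigma_r < 0:
            raise ValueError("sigma_r must be non-negative")

    @property
    def sigma(self) -> float:
        return self.sigma_r


LearnerConfig = Union[ZerothConfig, FirstConfig, SecondConfig]


# ---------------------------------------------------------------------------
# States and per-shot records
# ---------------------------------------------------------------------------


@dataclass
class ZerothState:
    w: float
    b: float
    config: ZerothConfig
    L_prev: float = None  # type: ignore[assignment]


@dataclass
class FirstState:
    m_est: float
    s_est: float
    config: FirstConfig

    @property
    def w(self) -> float:
        return 1.0 / self.m_est

    @property
    def b(self) -> float:
        return -self.s_est / self.m_est


@dataclass
class SecondState:
    m_est: float
    s_est: float
    config: SecondConfig
    P: np.ndarray = field(default_factory=lambda: np.eye(2))

    @property
    def w(self) -> float:
        return 1.0 / self.m_est

    @property
    def b(self) -> float:
        return -self.s_est / self.m_est


@dataclass(frozen=True)
class ShotRecord:
    """One shot: target x, action j, cursor c, signed error e = c - x, loss L = e^2."""

    block: int
    shot: int  # 1-based
    x: float
    j: float
    c: float
    e: float
    L: float
    noise_draw: float


def init_state(config: LearnerConfig, w0: float, b0: float):
    """Fresh start-of-block state at the calibrated initial policy (w0, b0)."""
    if config.order == "zeroth":
        return ZerothState(w=w0, b=b0, config=config)
    m_est, s_est = 1.0 / w0, -b0 / w0
    if config.order == "first":
        return FirstState(m_est, s_est, config)
    return SecondState(m_est, s_est, config)


# ---------------------------------------------------------------------------
# Scalar per-shot operations (reference implementation)
# ---------------------------------------------------------------------------


def act(state, x: float, rng: np.random.Generator):
    """Choose a joystick position: j = w*x + b + noise.

    The noise is the perturbation g (zeroth order) or the response
    variability r (first/second order).  Returns ``(j, noise_draw)``.
    """
    sigma = state.config.sigma
    n = rng.normal(0.0, sigma) if sigma > 0 else 0.0
    return state.w * x + state.b + n, n


def _clip_policy(w: float, b: float):
    return min(max(w, W_LO), W_HI), min(max(b, B_LO), B_HI)


def update_zeroth(state: ZerothState, record: ShotRecord) -> ZerothState:
    """Node-perturbation update; no update on the first shot of a block."""
    if state.L_prev is None:
        state.L_prev = record.L
        return state
    dL = record.L - state.L_prev
    cfg = state.config
    w = state.w - cfg.eta_w * dL * record.noise_draw * record.x
    b = state.b - cfg.eta_bias * dL * record.noise_draw
    state.w, state.b = _clip_policy(w, b)
    state.L_prev = record.L
    return state


def _reclip_estimates(state):
    """Derive (w, b) from the estimates, clip, and back-correct the estimates."""
    if state.m_est == 0.0:
        raise DegenerateEstimateError("m_est collapsed to zero")
    w, b = _clip_policy(1.0 / state.m_est, -state.s_est / state.m_est)
    state.m_est = 1.0 / w
    state.s_est = -b / w
    return state


def update_first(state: FirstState, record: ShotRecord) -> FirstState:
    """LMS update on the mapping estimates, then clip the derived policy."""
    cfg = state.config
    state.m_est += cfg.eta_m * record.e * record.j
    state.s_est += cfg.eta_s * record.e
    return _reclip_estimates(state)


def update_second(state: SecondState, record: ShotRecord) -> SecondState:
    """RLS update: gain from P, rank-one P downdate, then clip the policy."""
    cfg = state.config
    y = np.array([record.j, 1.0])
    v = state.P @ y
    denom = cfg.mu + y @ v
    if denom <= 0:
        raise DegenerateEstimateError("RLS denominator mu + y'Py <= 0")
    k = v / denom
    state.P = state.P - np.outer(v, k)
    if cfg.textbook_update:
        state.P = state.P / cfg.mu
    state.m_est += record.e * k[0]
    state.s_est += record.e * k[1]
    return _reclip_estimates(state)


def update(state, record: ShotRecord):
    """Dispatch to the order-specific update rule."""
    if isinstance(state, ZerothState):
        return update_zeroth(state, record)
    if isinstance(state, FirstState):
        return update_first(state, record)
    return update_second(state, record)


def run_block(
    config: LearnerConfig,
    w0: float,
    b0: float,
    mapping: Mapping,
    targets: np.ndarray,
    rng: np.random.Generator,
    block_index: int = 0,
) -> list:
    """Run one block shot by shot, starting fresh at (w0, b0).

    Returns one immutable :class:`ShotRecord` per target.  The state evolves
    by the learner's update after every shot.
    """
    state = init_state(config, w0, b0)
    records = []
    for t, x in enumerate(np.asarray(targets, dtype=float)):
        j, n = act(state, x, rng)
        c = mapping.m * j + mapping.s  # no joystick clipping in simulation
        e = c - x
        rec = ShotRecord(block=block_index, shot=t + 1, x=x, j=j, c=c, e=e, L=e * e, noise_draw=n)
        records.append(rec)
        update(state, rec)
    return records


# ---------------------------------------------------------------------------
# Vectorized engine
# ---------------------------------------------------------------------------


def _clip_arrays(w, b):
    np.clip(w, W_LO, W_HI, out=w)
    np.clip(b, B_LO, B_HI, out=b)
    return w, b


def simulate_blocks(
    config: LearnerConfig,
    w0,
    b0,
    m: np.ndarray,
    s: np.ndarray,
    targets: np.ndarray,
    z: np.ndarray,
) -> np.ndarray:
    """Run many independent blocks in parallel; returns unsigned errors (lanes, shots).

    Parameters
    ----------
    w0, b0 : float or (lanes,) arrays
        Start-of-block policy for every lane.
    m, s : (lanes,) arrays
        Block mappings, one per lane.
    targets : (lanes, shots) array
    z : (lanes, shots) array
        Standard-normal draws; scaled internally by the learner's sigma so the
        same stream serves common-random-number comparisons across sigmas.
    """
    m = np.asarray(m, float)
    s = np.asarray(s, float)
    targets = np.asarray(targets, float)
    z = np.asarray(z, float)
    lanes, shots = targets.shape
    noise = config.sigma * z
    errors = np.empty((lanes, shots))

    if config.order == "zeroth":
        w = np.full(lanes, w0, float) if np.isscalar(w0) else np.array(w0, float)
        b = np.full(lanes, b0, float) if np.isscalar(b0) else np.array(b0, float)
        L_prev = None
        for t in range(shots):
            x, g = targets[:, t], noise[:, t]
            j = w * x + b + g
            e = m * j + s - x
            L = e * e
            if L_prev is not None:
                dL = L - L_prev
                w -= config.eta_w * dL * g * x
                b -= config.eta_bias * dL * g
                _clip_arrays(w, b)
            L_prev = L
            errors[:, t] = np.abs(e)
        return errors

    # first / second order share the estimate bookkeeping
    w = np.full(lanes, w0, float) if np.isscalar(w0) else np.array(w0, float)
    b = np.full(lanes, b0, float) if np.isscalar(b0) else np.array(b0, float)
    m_est = 1.0 / w
    s_est = -b / w
    if config.order == "second":
        p11 = np.ones(lanes)
        p12 = np.zeros(lanes)
        p21 = np.zeros(lanes)
        p22 = np.ones(lanes)

    tiny = np.finfo(float).tiny
    for t in range(shots):
        x, r = targets[:, t], noise[:, t]
        j = w * x + b + r
        e = m * j + s - x
        errors[:, t] = np.abs(e)
        if config.order == "first":
            m_est = m_est + config.eta_m * e * j
            s_est = s_est + config.eta_s * e
        else:
            v1 = p11 * j + p12
            v2 = p21 * j + p22
            denom = config.mu + j * v1 + v2
            k1 = v1 / denom
            k2 = v2 / denom
            p11 = p11 - v1 * k1
            p12 = p12 - v1 * k2
            p21 = p21 - v2 * k1
            p22 = p22 - v2 * k2
            if config.textbook_update:
                inv_mu = 1.0 / config.mu
                p11 *= inv_mu
                p12 *= inv_mu
                p21 *= inv_mu
                p22 *= inv_mu
            m_est = m_est + e * k1
            s_est = s_est + e * k2
        # clip the derived policy, back-correct the estimates
        m_safe = np.where(m_est == 0.0, tiny, m_est)
        w = 1.0 / m_safe
        b = -s_est / m_safe
        _clip_arrays(w, b)
        m_est = 1.0 / w
        s_est = -b / w
    return errors


def run_experiment(
    config: LearnerConfig,
    design: ExperimentDesign,
    w0: float,
    b0: float,
    n_reps: int,
    rng: np.random.Generator,
    chunk_reps: int = 20_000,
) -> np.ndarray:
    """Repeat the 24-test-block experiment ``n_reps`` times.

    Returns a (n_reps, 15) array: for each repetition, the mean unsigned error
    per shot averaged over the 24 test blocks.  The learner restarts at
    (w0, b0) at every block; only the noise stream differs across repetitions.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    m, s, x = design.test_arrays()
    n_blocks, shots = x.shape
    curves = np.empty((n_reps, shots))
    done = 0
    while done < n_reps:
        k = min(chunk_reps, n_reps - done)
        mm = np.tile(m, k)
        ss = np.tile(s, k)
        xx = np.tile(x, (k, 1))
        z = rng.standard_normal((k * n_blocks, shots))
        err = simulate_blocks(config, w0, b0, mm, ss, xx, z)
        curves[done : done + k] = err.reshape(k, n_blocks, shots).mean(axis=1)
        done += k
    return curves


def curves_to_csv(curves: np.ndarray, path) -> None:
    """Write per-repetition error curves in long form (repetition, shot, mean_error)."""
    curves = np.asarray(curves)
    n_reps, shots = curves.shape
    with open(path, "w") as fh:
        fh.write("repetition,shot,mean_error\n")
        for r in range(n_reps):
            for t in range(shots):
                fh.write(f"{r + 1},{t + 1},{float(curves[r, t])!r}\n")


def run_long_block(
    config: LearnerConfig,
    block: Block,
    w0: float,
    b0: float,
    n_reps: int,
    rng: np.random.Generator = None,
    z: np.ndarray = None,
) -> np.ndarray:
    """Simulate the 100-shot long block ``n_reps`` times; returns |e| (n_reps, 100).

    Either ``rng`` (fresh noise) or ``z`` (a fixed standard-normal array for
    common-random-number reuse) must be given.
    """
    shots = block.n_shots
    if z is None:
        z = rng.standard_normal((n_reps, shots))
    m = np.full(n_reps, block.mapping.m)
    s = np.full(n_reps, block.mapping.s)
    x = np.tile(block.targets, (n_reps, 1))
    return simulate_blocks(config, w0, b0, m, s, x, z)
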