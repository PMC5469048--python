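"""Subject-matched calibration of doppelganger learners.

Each simulated learner is matched to its (synthetic) human in two ways:

* an initial policy (w0, b0) whose mean unsigned error on shot 1 across the
  24 test blocks equals the human's mean first-shot error, and
* (first/second order only) a response-noise SD sigma_r such that the
  simulated median unsigned error over shots 51-100 of the human's 100-shot
  long block equals the human's.

The (w0, b0) problem is under-determined (one scalar constraint, two
parameters); we fix b0 = 0 (the centre of its range) and solve for w0.
Because the mean first-shot error is an average of |affine functions of w0|
it is convex in w0, so we locate its minimizer and root-find on one branch.
"""
from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy.optimize import brentq, minimize, minimize_scalar

from .learners import FirstConfig, LearnerConfig, SecondConfig, run_long_block
from .task import B_STAR_RANGE, Block, ExperimentDesign, W_STAR_RANGE

__all__ = [
    "InfeasibleTargetError",
    "long_term_accuracy",
    "first_shot_error",
    "fit_initial_params",
    "fit_sigma_r",
    "HALF_NORMAL_MEDIAN",
]

#: Median of |N(0, 1)|, i.e. Phi^-1(0.75): median |e| = sigma * this at convergence (m=1).
HALF_NORMAL_MEDIAN = 0.6744897501960817


class InfeasibleTargetError(ValueError):
    """The requested calibration target cannot be achieved by any parameter value."""


def long_term_accuracy(long_block_errors) -> float:
    """Mean unsigned error over shots 51-100 (1-based) of the 100-shot long block."""
    e = np.asarray(long_block_errors, dtype=float)
    if e.shape != (100,):
        raise ValueError(f"expected 100 long-block errors, got shape {e.shape}")
    return float(np.mean(e[50:100]))


def first_shot_error(
    design: ExperimentDesign,
    w0: float,
    b0: float,
    sigma: float = 0.0,
    z: np.ndarray = None,
) -> float:
    """Mean unsigned shot-1 error across the test blocks at policy (w0, b0).

    Shot 1 happens before any update, so the error is available in closed
    form: e = m*(w0*x + b0 + sigma*z) + s - x.  With ``sigma > 0`` the mean is
    a Monte-Carlo expectation over the supplied standard-normal draws ``z``
    (shape (reps, n_blocks)); with ``sigma == 0`` it is exact.
    """
    m, s, x = design.test_arrays()
    x1 = x[:, 0]
    det = m * (w0 * x1 + b0) + s - x1
    if sigma == 0.0 or z is None:
        return float(np.mean(np.abs(det)))
    return float(np.mean(np.abs(det[None, :] + sigma * m[None, :] * z)))


def fit_initial_params(
    target_first_shot_error: float,
    design: ExperimentDesign,
    sigma: float = 0.0,
    mc_reps: int = 2000,
    rng: np.random.Generator = None,
    b0: float = 0.0,
    tol: float = 1e-3,
    on_infeasible: str = "raise",
):
    """Find (w0, b0) whose mean shot-1 error matches the target.

    b0 is held fixed (default 0) and w0 solved by root-finding on the convex
    error profile, preferring the branch right of the minimizer.  With
    ``sigma > 0`` the profile is a common-random-numbers Monte-Carlo
    expectation over ``mc_reps`` repetitions of the learner's own first-shot
    noise.

    When the target lies below the b0-fixed minimum but is still achievable
    with a free bias, (w0, b0) is instead moved jointly along the segment
    between the design's two-parameter least-error point and the b0-fixed
    minimizer (the error is convex along the segment, so the crossing is
    unique).

    Raises
    ------
    InfeasibleTargetError
        If the target lies below the profile's minimum or above its maximum
        over w0 in [0.25, 1.75].  With ``on_infeasible="clamp"`` the closest
        achievable w0 is returned instead (with a warning); useful when the
        learner's own noise floor sits just above a subject's target.
    """
    if target_first_shot_error < 0:
        raise ValueError("target error must be non-negative")
    z = None
    if sigma > 0:
        if rng is None:
            raise ValueError("rng required when sigma > 0")
        z = rng.standard_normal((mc_reps, design.n_test))

    lo, hi = W_STAR_RANGE

    def profile(w0):
        return first_shot_error(design, w0, b0, sigma, z)

    res = minimize_scalar(profile, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
    w_min, f_min = float(res.x), float(res.fun)
    f_lo, f_hi = profile(lo), profile(hi)
    target = target_first_shot_error
    if target < f_min - tol:
        # the subject is more accurate than any fixed-b0 start: free the bias
        def profile2(p):
            return first_shot_error(design, p[0], p[1], sigma, z)

        # nested convex minimization: inner over w0, outer over b0
        def best_w(bb):
            r = minimize_scalar(lambda w: profile2((w, bb)), bounds=W_STAR_RANGE,
                                method="bounded", options={"xatol": 1e-10})
            return float(r.x), float(r.fun)

        outer = minimize_scalar(lambda bb: best_w(bb)[1], bounds=B_STAR_RANGE,
                                method="bounded", options={"xatol": 1e-10})
        b_j = float(outer.x)
        w_j, f_joint = best_w(b_j)
        if target < f_joint - tol:
            if on_infeasible == "clamp":
                warnings.warn(
                    f"first-shot target {target:.4g} below the achievable minimum "
                    f"{f_joint:.4g}; clamping to the least-error (w0, b0)"
                )
                return w_j, b_j
            raise InfeasibleTargetError(
                f"target {target:.4g} below the achievable minimum {f_joint:.4g}"
            )

        def seg(t):
            return profile2(((1 - t) * w_j + t * w_min, (1 - t) * b_j + t * b0))

        t = brentq(lambda u: seg(u) - min(max(target, f_joint), seg(1.0)), 0.0, 1.0,
                   xtol=1e-12)
        return float((1 - t) * w_j + t * w_min), float((1 - t) * b_j + t * b0)
    if target > max(f_lo, f_hi) + tol:
        if on_infeasible == "clamp":
            warnings.warn(
                f"first-shot target {target:.4g} above the achievable maximum; "
                "clamping to the worst-error endpoint"
            )
            return (lo if f_lo >= f_hi else hi), float(b0)
        raise InfeasibleTargetError(
            f"target {target:.4g} above the achievable maximum {max(f_lo, f_hi):.4g}"
        )
    target = min(max(target, f_min), max(f_lo, f_hi))
    # prefer the branch right of the minimizer (w0 above the best-matching weight)
    if f_hi >= target >= f_min and w_min < hi:
        w0 = brentq(lambda w: profile(w) - target, w_min, hi, xtol=1e-12)
    else:
        w0 = brentq(lambda w: profile(w) - target, lo, w_min, xtol=1e-12)
    return float(w0), float(b0)


def fit_sigma_r(
    target_median_error: float,
    config: LearnerConfig,
    w0: float,
    b0: float,
    long_block: Block,
    mc_reps: int = 200,
    rng: np.random.Generator = None,
    rel_tol: float = 0.01,
    sigma_max: float = 2.0,
    on_infeasible: str = "raise",
) -> float:
    """Response-noise SD matching the human's median long-block error.

    Simulates the same 100-shot long block (same mapping and targets) with
    learning on, and root-finds the sigma_r whose pooled median unsigned error
    over shots 51-100 matches ``target_median_error`` to relative tolerance
    ``rel_tol``.  Common random numbers (one fixed standard-normal array,
    rescaled by sigma_r) make the profile continuous and monotone.
    """
    if not isinstance(config, (FirstConfig, SecondConfig)):
        raise ValueError("sigma_r applies to first- and second-order learners only")
    if target_median_error < 0:
        raise ValueError("target median must be non-negative")
    if target_median_error == 0.0:
        warnings.warn("target median 0 implies a fully converged, noise-free learner")
        return 0.0
    if rng is None:
        raise ValueError("rng required")
    z = rng.standard_normal((mc_reps, long_block.n_shots))

    def median_at(sig: float) -> float:
        cfg = replace(config, sigma_r=sig)
        err = run_long_block(cfg, long_block, w0, b0, mc_reps, z=z)
        return float(np.median(err[:, 50:100]))

    base = median_at(0.0)
    if target_median_error < base * (1 - rel_tol):
        if on_infeasible == "clamp":
            warnings.warn(
                f"long-block target {target_median_error:.4g} below the noiseless "
                f"floor {base:.4g}; clamping sigma_r to 0"
            )
            return 0.0
        raise InfeasibleTargetError(
            f"target {target_median_error:.4g} below the noiseless floor {base:.4g}"
        )
    hi = 0.1
    while median_at(hi) < target_median_error:
        hi *= 2.0
        if hi > sigma_max:
            raise InfeasibleTargetError(
                f"target {target_median_error:.4g} unreachable below sigma_r={sigma_max}"
            )
    sigma = brentq(
        lambda s: median_at(s) - target_median_error,
        0.0,
        hi,
        xtol=1e-8,
        rtol=1e-6,
    )
    return float(sigma)
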