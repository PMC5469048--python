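"""The statistical contest between humans and their doppelgangers.

The contest statistic is the *early error*: the mean unsigned shooting error
over shots 3-7, averaged across the 24 test blocks.  Significance is assessed
brute-force: the doppelganger repeats the whole 24-block experiment many
times and the empirical p-value is the fraction of repetitions achieving an
early error at least as small as the human's.  A zero count is reported as an
explicit upper bound p < 1/n_reps, never as 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.stats import wilcoxon

from .learners import run_experiment

__all__ = [
    "ErrorCurve",
    "ContestResult",
    "early_error",
    "brute_force_p",
    "group_contest",
    "per_shot_contest",
    "variability_scaling_contest",
    "running_average",
    "meta_learning_check",
    "MetaLearningResult",
    "mean_difference_permutation_p",
]

EARLY_SHOTS = (3, 7)  # 1-based inclusive window


@dataclass(frozen=True)
class ErrorCurve:
    """Per-shot mean unsigned errors across a subject's test blocks."""

    values: np.ndarray
    n_blocks: int = 24

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or len(v) < 7:
            raise ValueError("an error curve needs at least 7 shots")
        if np.any(v < 0):
            raise ValueError("error curve values must be non-negative")

    @property
    def early(self) -> float:
        return early_error(self.values)


def early_error(curve) -> float:
    """Mean of the curve over shots 3-7 (1-based, inclusive)."""
    v = np.asarray(curve, dtype=float)
    if v.ndim != 1 or len(v) < EARLY_SHOTS[1]:
        raise ValueError("curve must cover at least 7 shots")
    return float(np.mean(v[EARLY_SHOTS[0] - 1 : EARLY_SHOTS[1]]))


@dataclass(frozen=True)
class ContestResult:
    """Outcome of one human-vs-doppelganger early-error contest."""

    human_early: float
    count_leq: int
    n_reps: int
    dopp_mean: float
    dopp_sd: float
    dopp_min: float
    dopp_max: float
    count_geq: int = None  # repetitions at least as BAD as the human
    samples: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not (0 <= self.count_leq <= self.n_reps):
            raise ValueError("count_leq must be between 0 and n_reps")

    @property
    def is_bound(self) -> bool:
        """True when no repetition beat the human, so p is only an upper bound."""
        return self.count_leq == 0

    @property
    def p_value(self) -> float:
        """Human-outperforms tail: count_leq/n_reps (bound 1/n_reps on a zero count)."""
        return max(self.count_leq, 1) / self.n_reps

    @property
    def is_bound_loss(self) -> bool:
        return self.count_geq == 0

    @property
    def p_loss(self) -> float:
        """Human-loses tail: fraction of repetitions at least as bad as the human."""
        return max(self.count_geq, 1) / self.n_reps

    def __str__(self) -> str:
        p = f"p < {1 / self.n_reps:g}" if self.is_bound else f"p = {self.p_value:g}"
        return (
            f"human early error {self.human_early:.4f} vs doppelganger "
            f"{self.dopp_mean:.4f} [{self.dopp_min:.4f}, {self.dopp_max:.4f}] "
            f"({self.count_leq}/{self.n_reps} repetitions at least as good; {p})"
        )


def brute_force_p(human_early: float, dopp_samples, n_reps: int = None) -> ContestResult:
    """Empirical p-value: fraction of repetitions with early error <= the human's."""
    samples = np.asarray(dopp_samples, dtype=float)
    if samples.size == 0:
        raise ValueError("doppelganger sample list is empty")
    if n_reps is not None and n_reps != samples.size:
        raise ValueError(f"n_reps={n_reps} does not match {samples.size} samples")
    return ContestResult(
        human_early=float(human_early),
        count_leq=int(np.sum(samples <= human_early)),
        count_geq=int(np.sum(samples >= human_early)),
        n_reps=samples.size,
        dopp_mean=float(samples.mean()),
        dopp_sd=float(samples.std(ddof=1)) if samples.size > 1 else 0.0,
        dopp_min=float(samples.min()),
        dopp_max=float(samples.max()),
        samples=samples,
    )


def group_contest(human_earlies, dopp_early_matrix) -> ContestResult:
    """Cohort-level contest on cross-subject mean early errors.

    ``dopp_early_matrix`` is (n_reps, n_subjects): for each repetition the
    per-subject doppelganger early errors; its cross-subject mean is compared
    to the humans' cross-subject mean.
    """
    humans = np.asarray(human_earlies, dtype=float)
    matrix = np.asarray(dopp_early_matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != humans.size:
        raise ValueError(
            f"matrix shape {matrix.shape} does not match {humans.size} subjects"
        )
    return brute_force_p(humans.mean(), matrix.mean(axis=1))


def per_shot_contest(human_curve, dopp_curves) -> dict:
    """Shot-wise contests for every shot 2..15; returns {shot: ContestResult}."""
    human = np.asarray(human_curve, dtype=float)
    curves = np.asarray(dopp_curves, dtype=float)
    if curves.ndim != 2 or curves.shape[1] != human.size:
        raise ValueError("curve shapes are not aligned")
    return {
        shot: brute_force_p(human[shot - 1], curves[:, shot - 1])
        for shot in range(2, human.size + 1)
    }


def variability_scaling_contest(
    scale: float,
    fits,
    n_reps: int,
    rng: np.random.Generator,
):
    """Re-run the contests with each doppelganger's sigma_r scaled by ``scale``.

    ``fits`` is a list of fitted doppelgangers (:class:`~visuomotor.model.DoppelgangerResults`)
    of first or second order; hyperparameters are deliberately *not*
    re-optimized — the scaling is a perturbation of the fitted learner.
    Returns (early ContestResults per subject, per-shot contests per subject).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    early_results, shot_results = [], []
    for fit in fits:
        if fit.config.order == "zeroth":
            raise ValueError("zeroth-order learners have no response variability to scale")
        config = replace(fit.config, sigma_r=scale * fit.config.sigma_r)
        curves = run_experiment(
            config, fit.profile.design, fit.w0, fit.b0, n_reps, rng
        )
        earlies = curves[:, EARLY_SHOTS[0] - 1 : EARLY_SHOTS[1]].mean(axis=1)
        early_results.append(brute_force_p(early_error(fit.profile.error_curve), earlies))
        shot_results.append(per_shot_contest(fit.profile.error_curve, curves))
    return early_results, shot_results


def mean_difference_permutation_p(
    slower,
    faster,
    n_perm: int = 5000,
    rng: np.random.Generator = None,
    chunk: int = 200,
) -> float:
    """One-sided Monte-Carlo permutation test that mean(slower) > mean(faster).

    Permutes the group labels of the pooled per-repetition samples and
    returns (1 + #{permuted mean difference >= observed}) / (n_perm + 1), so a
    difference no permutation reaches reports the resolution bound.
    """
    a = np.asarray(slower, dtype=float)
    b = np.asarray(faster, dtype=float)
    if rng is None:
        rng = np.random.default_rng()
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n_a = a.size
    hits = 0
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((k, pooled.size)), axis=1)
        perm = pooled[idx]
        diff = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
        hits += int(np.sum(diff >= obs))
        done += k
    return (1 + hits) / (n_perm + 1)


def running_average(errors, window: int = 9) -> np.ndarray:
    """Centred moving average with the window truncated symmetrically at the ends."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    x = np.asarray(errors, dtype=float)
    n = len(x)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = x[i - h : i + h + 1].mean()
    return out


class MetaLearningResult(NamedTuple):
    p_value: float
    statistic: float
    degenerate: bool


def meta_learning_check(early_errors_first6, early_errors_last6) -> MetaLearningResult:
    """Two-sided exact Wilcoxon signed-rank test on paired block-group early errors.

    Tests whether subjects' early errors differ between the first six and the
    final six test blocks — evidence of learning-to-learn across blocks.
    """
    a = np.asarray(early_errors_first6, dtype=float)
    b = np.asarray(early_errors_last6, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if np.all(d == 0):
        return MetaLearningResult(p_value=1.0, statistic=0.0, degenerate=True)
    method = "exact" if len(d) <= 25 else "auto"
    res = wilcoxon(a, b, alternative="two-sided", method=method)
    return MetaLearningResult(p_value=float(res.pvalue), statistic=float(res.statistic), degenerate=False)
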