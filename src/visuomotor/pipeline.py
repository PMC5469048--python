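"""Orchestration: cohort -> calibrate/optimize -> contests -> robustness -> report.

All randomness descends from one root seed through named
``numpy.random.SeedSequence`` children, so a given configuration reproduces
its reports byte for byte.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contest import (
    EARLY_SHOTS,
    brute_force_p,
    early_error,
    group_contest,
    meta_learning_check,
    per_shot_contest,
    variability_scaling_contest,
)
from .model import Doppelganger, ORDERS
from .subjects import SyntheticHumanModel, export_cohort, make_cohort

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]

log = logging.getLogger("visuomotor")


@dataclass
class RunConfig:
    """Settings for one full replication run."""

    root_seed: int = 0
    n_subjects: int = 12
    n_reps: int = 10_000
    orders: tuple = ORDERS
    out_dir: str = "results"
    # cohort generator
    generator_kind: str = "first_order_noisy"
    # hyperopt / calibration
    mc_blocks: int = 2000
    n_starts: int = 5
    fit_rounds: int = 2
    # robustness
    variability_scales: tuple = (1.2, 1.35)
    run_robustness: bool = True

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_reps < 1:
            raise ValueError("counts must be positive")
        bad = set(self.orders) - set(ORDERS)
        if bad:
            raise ValueError(f"unknown orders: {bad}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("orders", "variability_scales"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["orders"] = list(self.orders)
        d["variability_scales"] = list(self.variability_scales)
        return d


@dataclass
class PipelineResult:
    cohort: list
    fits: dict  # (subject_id, order) -> DoppelgangerResults
    contests: pd.DataFrame
    group: dict
    out_dir: Path


def _seed(root: int, *names) -> np.random.Generator:
    """Deterministic child stream for a named pipeline stage."""
    tokens = [root] + [
        zlib.crc32(n.encode()) if isinstance(n, str) else int(n) for n in names
    ]
    return np.random.default_rng(np.random.SeedSequence(tokens))


def _stage(name):
    log.info("stage: %s", name)
    return time.perf_counter()


def build_cohort(config: RunConfig):
    model = SyntheticHumanModel(generator_kind=config.generator_kind)
    rng = _seed(config.root_seed, "cohort")
    return make_cohort(config.n_subjects, model, rng), model


def fit_doppelgangers(config: RunConfig, cohort) -> dict:
    fits = {}
    for sd in cohort:
        for order in config.orders:
            rng = _seed(config.root_seed, "fit", order, sd.profile.subject_id)
            model = Doppelganger.from_subject(sd, order)
            fits[(sd.profile.subject_id, order)] = model.fit(
                rng,
                mc_blocks=config.mc_blocks,
                n_starts=config.n_starts,
                rounds=config.fit_rounds,
            )
    return fits


def run_contests(config: RunConfig, cohort, fits):
    """Individual and group contests for every order; returns (table, group dict, raw)."""
    rows = []
    group = {}
    raw = {}  # (sid, order) -> (curves-derived early samples, curves)
    for order in config.orders:
        early_matrix = []
        human_earlies = []
        for sd in cohort:
            sid = sd.profile.subject_id
            fit = fits[(sid, order)]
            rng = _seed(config.root_seed, "contest", order, sid)
            curves = fit.simulate(config.n_reps, rng)
            earlies = curves[:, EARLY_SHOTS[0] - 1 : EARLY_SHOTS[1]].mean(axis=1)
            human_early = early_error(sd.profile.error_curve)
            res = brute_force_p(human_early, earlies)
            raw[(sid, order)] = (earlies, curves)
            early_matrix.append(earlies)
            human_earlies.append(human_early)
            rows.append(
                {
                    "subject": sid,
                    "order": order,
                    "human_early": human_early,
                    "dopp_mean": res.dopp_mean,
                    "dopp_sd": res.dopp_sd,
                    "dopp_min": res.dopp_min,
                    "dopp_max": res.dopp_max,
                    "count_leq": res.count_leq,
                    "n_reps": res.n_reps,
                    "p_or_bound": res.p_value,
                    "is_bound": res.is_bound,
                    "p_loss_or_bound": res.p_loss,
                    "is_bound_loss": res.is_bound_loss,
                }
            )
        gres = group_contest(human_earlies, np.column_stack(early_matrix))
        group[order] = {
            "human_mean_early": gres.human_early,
            "dopp_mean_early": gres.dopp_mean,
            "count_leq": gres.count_leq,
            "n_reps": gres.n_reps,
            "p_or_bound": gres.p_value,
            "is_bound": gres.is_bound,
            "p_loss_or_bound": gres.p_loss,
            "is_bound_loss": gres.is_bound_loss,
        }
    return pd.DataFrame(rows), group, raw


def run_robustness(config: RunConfig, cohort, fits, raw):
    """Per-shot contests, variability scaling, and the meta-learning check."""
    out = {}
    # per-shot contests at group level, per order
    per_shot = {}
    for order in config.orders:
        shot_p = {}
        for sd in cohort:
            sid = sd.profile.subject_id
            _, curves = raw[(sid, order)]
            contests = per_shot_contest(sd.profile.error_curve, curves)
            for shot, res in contests.items():
                shot_p.setdefault(shot, []).append(res.p_value)
        per_shot[order] = {shot: ps for shot, ps in sorted(shot_p.items())}
    out["per_shot_p"] = per_shot

    # variability scaling (first/second order only)
    scaling = {}
    for order in config.orders:
        if order == "zeroth":
            continue
        for scale in config.variability_scales:
            rng = _seed(config.root_seed, "robustness", order, int(scale * 100))
            flist = [fits[(sd.profile.subject_id, order)] for sd in cohort]
            early_res, _ = variability_scaling_contest(scale, flist, config.n_reps, rng)
            scaling[f"{order}_x{scale}"] = [
                {"subject": sd.profile.subject_id, "p_or_bound": r.p_value,
                 "is_bound": r.is_bound, "dopp_mean": r.dopp_mean}
                for sd, r in zip(cohort, early_res)
            ]
    out["variability_scaling"] = scaling

    # meta-learning check on the synthetic humans' first vs last six test blocks
    first6, last6 = [], []
    for sd in cohort:
        test = sd.records[sd.records.phase == "test"]
        by_block = test.groupby("block").apply(
            lambda df: early_error(df.sort_values("shot")["error"].to_numpy()),
            include_groups=False,
        )
        first6.append(by_block.loc[1:6].mean())
        last6.append(by_block.loc[19:24].mean())
    ml = meta_learning_check(first6, last6)
    out["meta_learning"] = {
        "p_value": ml.p_value,
        "statistic": ml.statistic,
        "degenerate": ml.degenerate,
    }
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full study and write all reports under ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    t0 = _stage("cohort")
    cohort, model = build_cohort(config)
    export_cohort(cohort, out_dir / "cohort", root_seed=config.root_seed, model=model)
    log.info("cohort done in %.1fs", time.perf_counter() - t0)

    t0 = _stage("calibrate+optimize")
    fits = fit_doppelgangers(config, cohort)
    calib_rows = []
    for (sid, order), fit in sorted(fits.items()):
        calib_rows.append(
            {
                "subject": sid,
                "order": order,
                "w0": fit.w0,
                "b0": fit.b0,
                "sigma_r": fit.sigma_r,
                "target_first_shot_error": fit.profile.mean_first_shot_error,
                "target_long_median": fit.profile.median_long_error,
                "shot15_objective": fit.hyperopt.objective,
                **{f"hp_{k}": v for k, v in fit.hyperopt.params.items()},
            }
        )
    pd.DataFrame(calib_rows).to_csv(out_dir / "calibration.csv", index=False, float_format="%.10g")
    log.info("fits done in %.1fs", time.perf_counter() - t0)

    t0 = _stage("contests")
    contests, group, raw = run_contests(config, cohort, fits)
    contests.to_csv(out_dir / "contests.csv", index=False, float_format="%.10g")
    log.info("contests done in %.1fs", time.perf_counter() - t0)

    extras = {}
    if config.run_robustness:
        t0 = _stage("robustness")
        extras = run_robustness(config, cohort, fits, raw)
        log.info("robustness done in %.1fs", time.perf_counter() - t0)

    cfg_dict = config.to_dict()
    cfg_dict.pop("out_dir")  # keep reports byte-identical regardless of location
    manifest = {
        "package_version": __version__,
        "config": cfg_dict,
        "group_contests": group,
        **extras,
    }
    (out_dir / "report.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(cohort=cohort, fits=fits, contests=contests, group=group, out_dir=out_dir)
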