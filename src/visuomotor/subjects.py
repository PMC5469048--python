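"""Synthetic 12-subject cohort emulating the human shooting data.

No raw human data from the original experiment is publicly available, so the
cohort here is generated.  The default surrogate is a deliberately suboptimal
first-order (LMS) learner — human performance sits nearest the first-order
curve — with per-subject response noise drawn from the reported human range
sigma_r in [0.0481, 0.0942] and learning rates degraded by a per-subject
factor eta_scale in (0, 1].  A mechanism-free alternative
(``parametric_curve``) generates exponential-decay error curves directly.

Each subject performs the full protocol: 6 warmup blocks (excluded from
analysis), 24 test blocks of 15 shots, and a 100-shot long block after test
block 14, each block under a fresh random magnify-and-shift mapping.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .learners import FirstConfig, run_block
from .task import ExperimentDesign

__all__ = ["SyntheticHumanModel", "SubjectProfile", "SubjectData", "make_cohort", "export_cohort", "import_cohort"]

#: Reference (undegraded) LMS rates: a one-off shot-15 optimization at the
#: cohort-mean response noise (sigma_r = 0.0705) from w0=1, b0=0, constrained
#: to the stable-rate box; subjects use eta_scale times them.
ETA_M_REF = 2.0
ETA_S_REF = 0.18


@dataclass(frozen=True)
class SyntheticHumanModel:
    """Generator settings for the synthetic cohort."""

    generator_kind: str = "first_order_noisy"  # or "parametric_curve"
    sigma_r_range: tuple = (0.0481, 0.0942)
    eta_scale_range: tuple = (0.4, 0.9)
    eta_m_ref: float = ETA_M_REF
    eta_s_ref: float = ETA_S_REF
    w0_range: tuple = (0.6, 1.45)
    b0_range: tuple = (-0.1, 0.1)
    # parametric_curve only: error decays from the first-shot level to an
    # asymptote with this shot time-constant
    curve_tau_shots: float = 2.5

    def __post_init__(self):
        if self.generator_kind not in ("first_order_noisy", "parametric_curve"):
            raise ValueError(f"unknown generator_kind {self.generator_kind!r}")
        lo, hi = self.eta_scale_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("eta_scale_range must lie in (0, 1]")


@dataclass
class SubjectProfile:
    """One (synthetic) human's calibration summary.

    ``w0``, ``b0`` and ``sigma_r`` are the *calibrated* doppelganger
    parameters; they are None until calibration has run.
    """

    subject_id: int
    mean_first_shot_error: float
    long_term_accuracy: float
    median_long_error: float
    error_curve: np.ndarray  # (15,) mean |e| per shot over the 24 test blocks
    design: ExperimentDesign
    w0: float = None
    b0: float = None
    sigma_r: float = None

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "mean_first_shot_error": self.mean_first_shot_error,
            "long_term_accuracy": self.long_term_accuracy,
            "median_long_error": self.median_long_error,
            "error_curve": list(self.error_curve),
            "design": self.design.to_dict(),
            "w0": self.w0,
            "b0": self.b0,
            "sigma_r": self.sigma_r,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectProfile":
        return cls(
            subject_id=d["subject_id"],
            mean_first_shot_error=d["mean_first_shot_error"],
            long_term_accuracy=d["long_term_accuracy"],
            median_long_error=d["median_long_error"],
            error_curve=np.array(d["error_curve"]),
            design=ExperimentDesign.from_dict(d["design"]),
            w0=d["w0"],
            b0=d["b0"],
            sigma_r=d["sigma_r"],
        )


@dataclass
class SubjectData:
    """Profile plus the full simulated shot table and generator parameters."""

    profile: SubjectProfile
    records: pd.DataFrame  # columns: subject, phase, block, shot, x, j, c, error
    generator_params: dict = field(default_factory=dict)


def _phase_sequence(design: ExperimentDesign):
    """Blocks in protocol order: warmups, test 1..pos, long, test pos+1..24."""
    seq = [("warmup", i + 1, blk) for i, blk in enumerate(design.warmup_blocks)]
    pos = design.long_block_position
    seq += [("test", i + 1, blk) for i, blk in enumerate(design.test_blocks[:pos])]
    seq += [("long", 1, design.long_block)]
    seq += [("test", i + 1, blk) for i, blk in enumerate(design.test_blocks[pos:], start=pos)]
    return seq


def _simulate_subject_records(subject_id, design, config, w0g, b0g, rng) -> pd.DataFrame:
    rows = []
    for phase, block_no, blk in _phase_sequence(design):
        recs = run_block(config, w0g, b0g, blk.mapping, blk.targets, rng, block_index=block_no)
        for r in recs:
            rows.append((subject_id, phase, block_no, r.shot, r.x, r.j, r.c, abs(r.e)))
    return pd.DataFrame(rows, columns=["subject", "phase", "block", "shot", "x", "j", "c", "error"])


def _parametric_subject_records(subject_id, design, first_level, asymptote, tau, rng) -> pd.DataFrame:
    """Mechanism-free surrogate: |e| follows an exponential decay plus half-normal noise."""
    rows = []
    for phase, block_no, blk in _phase_sequence(design):
        for t, x in enumerate(blk.targets):
            level = asymptote + (first_level - asymptote) * np.exp(-t / tau)
            # signed error with mean |e| = level for a centred Gaussian
            e = rng.normal(0.0, level * np.sqrt(np.pi / 2.0))
            c = x + e
            j = (c - blk.mapping.s) / blk.mapping.m
            rows.append((subject_id, phase, block_no, t + 1, x, j, c, abs(e)))
    return pd.DataFrame(rows, columns=["subject", "phase", "block", "shot", "x", "j", "c", "error"])


def _summarize(subject_id, design, records) -> SubjectProfile:
    test = records[records.phase == "test"]
    long = records[records.phase == "long"].sort_values("shot")
    curve = test.groupby("shot")["error"].mean().to_numpy()
    long_err = long["error"].to_numpy()
    return SubjectProfile(
        subject_id=subject_id,
        mean_first_shot_error=float(test[test.shot == 1]["error"].mean()),
        long_term_accuracy=float(np.mean(long_err[50:100])),
        median_long_error=float(np.median(long_err[50:100])),
        error_curve=curve,
        design=design,
    )


def make_cohort(
    n_subjects: int,
    model: SyntheticHumanModel = None,
    rng: np.random.Generator = None,
) -> list:
    """Generate ``n_subjects`` synthetic humans, each with its own design.

    Returns a list of :class:`SubjectData`.  Per-subject heterogeneity:
    sigma_r ~ U over the reported human range, eta_scale ~ U(0.4, 0.9),
    initial policy (w0, b0) ~ U over modest ranges around the naive identity
    guess.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    model = model or SyntheticHumanModel()
    if rng is None:
        rng = np.random.default_rng()
    cohort = []
    for sid in range(1, n_subjects + 1):
        design = ExperimentDesign.sample(rng)
        sigma_r = rng.uniform(*model.sigma_r_range)
        eta_scale = rng.uniform(*model.eta_scale_range)
        w0g = rng.uniform(*model.w0_range)
        b0g = rng.uniform(*model.b0_range)
        gen = {
            "sigma_r": sigma_r,
            "eta_scale": eta_scale,
            "w0": w0g,
            "b0": b0g,
            "kind": model.generator_kind,
        }
        if model.generator_kind == "first_order_noisy":
            config = FirstConfig(
                eta_m=eta_scale * model.eta_m_ref,
                eta_s=eta_scale * model.eta_s_ref,
                sigma_r=sigma_r,
            )
            records = _simulate_subject_records(sid, design, config, w0g, b0g, rng)
        else:
            m, s, x = design.test_arrays()
            first_level = float(np.mean(np.abs(m * (w0g * x[:, 0] + b0g) + s - x[:, 0])))
            asymptote = sigma_r / 0.6745 * 0.8  # noise-floor-scale plateau
            records = _parametric_subject_records(
                sid, design, first_level, asymptote, model.curve_tau_shots, rng
            )
        cohort.append(SubjectData(_summarize(sid, design, records), records, gen))
    return cohort


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------


def export_cohort(cohort, outdir, root_seed=None, model: SyntheticHumanModel = None):
    """Write per-subject shot CSVs plus a JSON manifest; see :func:`import_cohort`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "root_seed": root_seed,
        "model": asdict(model) if model else None,
        "n_subjects": len(cohort),
        "subjects": [],
    }
    for sd in cohort:
        sid = sd.profile.subject_id
        csv_path = outdir / f"subject_{sid:02d}_shots.csv"
        sd.records.to_csv(csv_path, index=False, float_format="%.17g")
        manifest["subjects"].append(
            {
                "profile": sd.profile.to_dict(),
                "generator_params": sd.generator_params,
                "shots_csv": csv_path.name,
            }
        )
    (outdir / "cohort.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir / "cohort.json"


def import_cohort(manifest_path) -> list:
    """Rebuild a cohort from :func:`export_cohort` output (profiles bit-identical)."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    cohort = []
    for entry in manifest["subjects"]:
        profile = SubjectProfile.from_dict(entry["profile"])
        records = pd.read_csv(
            manifest_path.parent / entry["shots_csv"], float_precision="round_trip"
        )
        cohort.append(SubjectData(profile, records, entry["generator_params"]))
    return cohort
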