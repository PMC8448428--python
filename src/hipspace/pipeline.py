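"""End-to-end experiment orchestration with reproducible artifacts.

Stages mirror the virtual-population experiment: ``generate`` draws a
seeded synthetic cohort per sex and writes meshes plus the ground-truth
parameter table; ``measure`` computes the morphometric table and a
per-sex summary; ``gait`` sweeps the gait cycle and summarizes the
minimal distance and its phase; ``stats`` runs the sex-difference test,
the correlation table, CCA, PLSR and the +-k SD shape regression.

Every artifact directory carries a provenance file with the exact
configuration and seed; for one seed the whole pipeline is byte-stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mesh import read_mesh, write_mesh
from .model import build_pdm, save_model
from .morphometry import measure_cohort
from .kinematics import load_gait, ifd_trajectory
from .stats import (sex_difference_test, correlation_table, cca_shape_ifd,
                    plsr_variance_explained, shape_regression)
from .synthetic import generate_cohort, default_distributions, PARAM_NAMES

__all__ = ["RunConfig", "run_generate", "run_measure", "run_gait", "run_stats", "run_all"]

_FLOAT_FORMAT = "%.9g"


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    seed: int
    n: int = 2000
    sexes: tuple[str, ...] = ("female", "male")
    n_modes: int = 20
    variance_fraction: float | None = None
    gait: str = "normative"
    phase_step: float = 2.0
    noise_sd: float = 0.05
    coupling_scale: float = 1.0
    k_sd: float = 3.0
    save_meshes: bool = True
    output_dir: str = "hipspace_out"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("config: n must be >= 1")
        if self.seed is None:
            raise ValueError("config: a seed is required")
        self.sexes = tuple(self.sexes)
        for sex in self.sexes:
            if sex not in ("female", "male"):
                raise ValueError(f"config: unknown sex {sex!r}")
        if self.n_modes < 1:
            raise ValueError("config: n_modes must be >= 1")
        if not self.gait.startswith("normative") and not Path(self.gait).exists():
            raise FileNotFoundError(f"config: gait source {self.gait!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sexes"] = list(self.sexes)
        return d

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()

    def sex_dir(self, sex: str) -> Path:
        return Path(self.output_dir) / sex

    def sex_seed(self, sex: str) -> int:
        # stable per-sex substream, kept below 2**31
        return (int(self.seed) * 4 + ("female", "male").index(sex)) % (2 ** 31 - 1)


def _write_provenance(cfg: RunConfig, directory: Path, stage: str) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    payload = {"stage": stage, "seed": int(cfg.seed), "config": cfg.to_dict(),
               "config_sha256": cfg.digest(), "hipspace_version": __version__}
    (directory / f"provenance_{stage}.json").write_text(
        json.dumps(payload, sort_keys=True, indent=1))


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def _cohort(cfg: RunConfig, sex: str):
    dist = default_distributions(sex, coupling_scale=cfg.coupling_scale)
    return generate_cohort(sex, cfg.n, cfg.sex_seed(sex), noise_sd=cfg.noise_sd,
                           distributions=dist)


def run_generate(cfg: RunConfig, log=print) -> dict:
    """Generate cohorts and write meshes + ground-truth tables."""
    out = {}
    for sex in cfg.sexes:
        meshes, truth = _cohort(cfg, sex)
        sdir = cfg.sex_dir(sex)
        sdir.mkdir(parents=True, exist_ok=True)
        _write_csv(truth, sdir / "truth.csv")
        if cfg.save_meshes:
            mdir = sdir / "meshes"
            for i, (pelvis, femur) in enumerate(meshes):
                write_mesh(pelvis, mdir / f"sample_{i:05d}_pelvis.ply")
                write_mesh(femur, mdir / f"sample_{i:05d}_femur.ply")
        _write_provenance(cfg, sdir, "generate")
        log(f"[generate] {sex}: {len(meshes)} hips -> {sdir}")
        out[sex] = meshes
    return out


def _load_cohort(cfg: RunConfig, sex: str):
    mdir = cfg.sex_dir(sex) / "meshes"
    if not mdir.exists():
        raise FileNotFoundError(f"no generated cohort for {sex!r} under {mdir}; "
                                "run the generate stage first")
    pairs = []
    for i in range(cfg.n):
        pelvis = read_mesh(mdir / f"sample_{i:05d}_pelvis.ply")
        femur = read_mesh(mdir / f"sample_{i:05d}_femur.ply")
        pairs.append((pelvis, femur))
    return pairs


def _get_cohorts(cfg: RunConfig, cohorts=None) -> dict:
    if cohorts is not None:
        return cohorts
    return {sex: _load_cohort(cfg, sex) for sex in cfg.sexes}


def run_measure(cfg: RunConfig, cohorts=None, log=print) -> dict[str, pd.DataFrame]:
    """Morphometric table + per-sex mean/SD summary for every cohort."""
    cohorts = _get_cohorts(cfg, cohorts)
    tables = {}
    for sex in cfg.sexes:
        df = measure_cohort(cohorts[sex], sex=sex)
        sdir = cfg.sex_dir(sex)
        _write_csv(df, sdir / "morphometrics.csv")
        numeric = df.drop(columns=["sample_id", "sex"])
        summary = pd.DataFrame({"measure": numeric.columns,
                                "mean": numeric.mean().to_numpy(),
                                "sd": numeric.std(ddof=1).to_numpy()})
        _write_csv(summary, sdir / "summary.csv")
        _write_provenance(cfg, sdir, "measure")
        log(f"[measure] {sex}: {len(df)} records -> {sdir / 'morphometrics.csv'}")
        tables[sex] = df
    return tables


def run_gait(cfg: RunConfig, cohorts=None, log=print) -> dict[str, pd.DataFrame]:
    """Distance trajectories across the gait cycle, per sample and summary."""
    cohorts = _get_cohorts(cfg, cohorts)
    summaries = {}
    for sex in cfg.sexes:
        gait = load_gait(cfg.gait, sex=sex)
        sdir = cfg.sex_dir(sex)
        tdir = sdir / "trajectories"
        rows = []
        for i, (pelvis, femur) in enumerate(cohorts[sex]):
            traj = ifd_trajectory(pelvis, femur, gait, phase_step=cfg.phase_step)
            _write_csv(pd.DataFrame({"phase_percent": traj.phase, "ifd_mm": traj.ifd}),
                       tdir / f"sample_{i:05d}.csv")
            rows.append({"sample_id": i, "min_ifd": traj.min_ifd, "min_phase": traj.min_phase})
        summary = pd.DataFrame(rows)
        _write_csv(summary, sdir / "gait_summary.csv")
        agg = {"sex": sex, "n": len(summary),
               "median_min_ifd": float(summary["min_ifd"].median()),
               "mean_min_ifd": float(summary["min_ifd"].mean()),
               "median_min_phase": float(summary["min_phase"].median())}
        (sdir / "gait_summary.json").write_text(json.dumps(agg, sort_keys=True, indent=1))
        _write_provenance(cfg, sdir, "gait")
        log(f"[gait] {sex}: median min IFD {agg['median_min_ifd']:.2f} mm "
            f"at {agg['median_min_phase']:.0f}% of the cycle")
        summaries[sex] = summary
    return summaries


def run_stats(cfg: RunConfig, cohorts=None, measures: dict | None = None, log=print) -> dict:
    """Sex difference, correlation table, CCA, PLSR and shape regression."""
    cohorts = _get_cohorts(cfg, cohorts)
    if measures is None:
        measures = {}
        for sex in cfg.sexes:
            path = cfg.sex_dir(sex) / "morphometrics.csv"
            if not path.exists():
                raise FileNotFoundError(f"missing {path}; run the measure stage first")
            measures[sex] = pd.read_csv(path)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    combined = pd.concat([measures[s] for s in cfg.sexes], ignore_index=True)
    corr = correlation_table(combined)
    _write_csv(corr, outdir / "correlation_table.csv")

    report: dict = {"seed": int(cfg.seed), "n_per_sex": cfg.n}
    if {"female", "male"} <= set(cfg.sexes):
        sd = sex_difference_test(measures["male"]["ischiofemoral_distance"],
                                 measures["female"]["ischiofemoral_distance"])
        report["sex_difference"] = dataclasses.asdict(sd)

    for sex in cfg.sexes:
        n_modes = min(cfg.n_modes, cfg.n - 1)
        retention = cfg.variance_fraction if cfg.variance_fraction is not None else n_modes
        pdm = build_pdm(cohorts[sex], retention, sex=sex)
        save_model(pdm, cfg.sex_dir(sex) / "pdm.npz")
        shapes = np.stack([np.concatenate([p.vertices.ravel(), f.vertices.ravel()])
                           for p, f in cohorts[sex]])
        weights = pdm.transform(shapes)
        scores = pdm.scores(weights, is_weights=True)
        ifd = measures[sex]["ischiofemoral_distance"].to_numpy(dtype=float)
        cca = cca_shape_ifd(pdm, scores, ifd)
        pls = plsr_variance_explained(ifd, weights)
        reg = shape_regression(pdm, weights, ifd, k_sd=cfg.k_sd)
        low, mean, high = reg.meshes(pdm)
        for tag, pair in (("low", low), ("mean", mean), ("high", high)):
            for bone, mesh in zip(("pelvis", "femur"), pair):
                write_mesh(mesh, cfg.sex_dir(sex) / f"consensus_{tag}_{bone}.ply")
        report[sex] = {
            "pdm_modes": pdm.n_modes_,
            "pdm_variance_fraction": pdm.explained_variance_fraction(),
            "cca_r": cca.r, "cca_p": cca.p_value,
            "plsr_percent_variance": pls.percent_variance_explained,
            "ifd_mean": float(ifd.mean()), "ifd_sd": float(ifd.std(ddof=1)),
        }
        log(f"[stats] {sex}: CCA r={cca.r:.3f}, PLSR {pls.percent_variance_explained:.2f}% "
            f"of shape variance")
    (outdir / "stats_summary.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    _write_provenance(cfg, outdir, "stats")
    return report


def run_all(cfg: RunConfig, log=print) -> dict:
    cohorts = run_generate(cfg, log=log)
    measures = run_measure(cfg, cohorts=cohorts, log=log)
    run_gait(cfg, cohorts=cohorts, log=log)
    return run_stats(cfg, cohorts=cohorts, measures=measures, log=log)
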