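"""File-level orchestration: simulate -> preprocess -> fit as restartable stages.

Each stage reads and writes plain CSV/YAML/JSON so it can be rerun or
swapped for real study data.  Bouts are long-format CSVs (subject_id,
t_index, x1, x2, x3); subject features are one wide row per subject with the
546 spectrum columns; the fit stage writes the coefficient-function report,
the scalar-coefficient table, a JSON run summary, and a beta(.)-with-bands
plot.  The effective configuration is echoed into every output directory so
a run can be reproduced from its artifacts alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .config import RunConfig
from .errors import InsufficientDataError, NoCadencePeakError, StructuralError
from .penalty import build_basis, penalty_operator, projection
from .preprocess import RawBout, SubjectFeatures, order_grid, process_bout
from .regression import assemble_design, fit_functional_model, significant_multiples
from .synthetic import CohortSpec, SimulateConfig, bump_beta, default_gait_sampler, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_simulate", "run_preprocess", "run_fit", "run_all",
           "write_bout", "read_bout", "features_to_frame", "frame_to_features"]


def write_bout(bout: RawBout, path: Path) -> None:
    pd.DataFrame(
        {
            "subject_id": bout.subject_id,
            "t_index": np.arange(len(bout)),
            "x1": bout.x1,
            "x2": bout.x2,
            "x3": bout.x3,
        }
    ).to_csv(path, index=False, float_format="%.8g")


def read_bout(path: Path, fs: float) -> RawBout:
    df = pd.read_csv(path)
    required = {"subject_id", "t_index", "x1", "x2", "x3"}
    if not required.issubset(df.columns):
        raise StructuralError(f"{path}: missing columns {required - set(df.columns)}")
    df = df.sort_values("t_index")
    return RawBout(
        subject_id=str(df["subject_id"].iloc[0]),
        fs=fs,
        x1=df["x1"].to_numpy(),
        x2=df["x2"].to_numpy(),
        x3=df["x3"].to_numpy(),
    )


def _spectrum_columns(grid: np.ndarray) -> list[str]:
    return [f"s_{s:.2f}" for s in grid]


def features_to_frame(features: list[SubjectFeatures]) -> pd.DataFrame:
    grid = features[0].order_grid
    rows = []
    for f in features:
        row = {"subject_id": f.subject_id, "cadence": f.cadence_hz, "vmc": f.vmc,
               "n_windows": f.n_windows, "n_dropped": f.n_dropped}
        row.update(dict(zip(_spectrum_columns(grid), f.spectrum)))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_features(df: pd.DataFrame, grid: np.ndarray) -> list[SubjectFeatures]:
    cols = _spectrum_columns(grid)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise StructuralError(f"features table missing {len(missing)} spectrum columns")
    return [
        SubjectFeatures(
            subject_id=str(r["subject_id"]),
            order_grid=grid,
            spectrum=np.array([r[c] for c in cols], dtype=float),
            cadence_hz=float(r["cadence"]),
            vmc=float(r["vmc"]),
            n_windows=int(r.get("n_windows", 0)),
            n_dropped=int(r.get("n_dropped", 0)),
        )
        for _, r in df.iterrows()
    ]


def _echo_config(cfg: RunConfig, outdir: Path) -> None:
    cfg.save(outdir / "config_used.yaml")


def run_simulate(cfg: RunConfig, outdir: str | Path) -> Path:
    """Write a synthetic cohort: per-subject bout CSVs, cohort.csv, truth.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = cfg.simulate
    grid = order_grid(cfg.preprocess)
    beta_true = bump_beta(grid, sim.beta_bump_center, sim.beta_bump_height, cfg.basis.sd)
    spec = CohortSpec(
        n_subjects=sim.n_subjects,
        gait_params_sampler=default_gait_sampler(sim),
        beta_true=beta_true,
        sigma_eps=sim.sigma_eps,
        seed=cfg.seed,
        preprocess=cfg.preprocess,
    )
    cohort = simulate_cohort(spec)
    bouts_dir = outdir / "bouts"
    bouts_dir.mkdir(exist_ok=True)
    for bout in cohort.bouts:
        write_bout(bout, bouts_dir / f"{bout.subject_id}.csv")
    cohort.covariates.to_csv(outdir / "cohort.csv", index=False, float_format="%.10g")
    truth = {
        "seed": cfg.seed,
        "n_subjects": sim.n_subjects,
        "sigma_eps": sim.sigma_eps,
        "gamma_true": [float(g) for g in cohort.gamma_true],
        "beta_bump_center": sim.beta_bump_center,
        "beta_bump_height": sim.beta_bump_height,
        "cadence_range": [sim.cadence_min, sim.cadence_max],
        "noise_sd": sim.noise_sd,
        "duration_s": sim.duration_s,
        "half_harmonics": sim.half_harmonics,
    }
    (outdir / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=False))
    _echo_config(cfg, outdir)
    logger.info("simulated %d subjects (seed %d) -> %s", sim.n_subjects, cfg.seed, outdir)
    return outdir


def run_preprocess(cfg: RunConfig, indir: str | Path, outdir: str | Path) -> Path:
    """Process every bout CSV under indir/bouts into the features table."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bout_paths = sorted((indir / "bouts").glob("*.csv"))
    if not bout_paths:
        raise InsufficientDataError(f"no bout CSVs under {indir / 'bouts'}")
    features, failed = [], []
    for path in bout_paths:
        bout = read_bout(path, fs=cfg.preprocess.fs)
        try:
            features.append(process_bout(bout, cfg.preprocess))
        except (NoCadencePeakError, InsufficientDataError) as exc:
            logger.warning("excluding subject %s: %s", bout.subject_id, exc)
            failed.append(bout.subject_id)
    if not features:
        raise NoCadencePeakError("all subjects failed pre-processing")
    features_to_frame(features).to_csv(outdir / "features.csv", index=False, float_format="%.10g")
    if failed:
        (outdir / "excluded_subjects.txt").write_text("\n".join(failed) + "\n")
    _echo_config(cfg, outdir)
    logger.info("preprocessed %d subjects (%d excluded) -> %s", len(features), len(failed), outdir)
    return outdir


def run_fit(cfg: RunConfig, features_dir: str | Path, cohort_csv: str | Path,
            outdir: str | Path) -> dict:
    """Fit the penalized scalar-on-function model and write the fit report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = order_grid(cfg.preprocess)
    features = frame_to_features(pd.read_csv(Path(features_dir) / "features.csv"), grid)
    covariates = pd.read_csv(cohort_csv)
    ds = assemble_design(features, covariates)

    b = cfg.basis
    basis = build_basis(grid, sd=b.sd, center_step=b.center_step,
                        center_min=b.center_min, center_max=b.center_max)
    offdiag = basis.max_offdiag_inner()
    if offdiag > b.orth_threshold:
        logger.warning("basis columns not nearly orthogonal: max inner %.3f > %.3f",
                       offdiag, b.orth_threshold)
    Lop = penalty_operator(projection(basis.Q), a=b.a)
    fit = fit_functional_model(ds, Lop)
    sig = significant_multiples(fit, basis.centers)

    pd.DataFrame(
        {"order": grid, "beta_hat": fit.beta_hat,
         "band_lower": fit.band_lower, "band_upper": fit.band_upper}
    ).to_csv(outdir / "fit_report.csv", index=False, float_format="%.10g")
    fit.scalar_table().to_csv(outdir / "scalar_coefficients.csv", index=False,
                              float_format="%.10g")
    summary = {
        "n_subjects": ds.n,
        "lambda": fit.lam,
        "sigma_eps2": fit.sigma_eps2,
        "sigma_beta2": fit.sigma_beta2,
        "significant_multiples": sig,
        "scalar_terms": dict(zip(fit.x_names, fit.gamma_hat.tolist())),
        "band_level": fit.level,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    _plot_beta(grid, fit, outdir / "beta_hat.png")
    _echo_config(cfg, outdir)
    logger.info("fit complete: lambda = %.4g, significant multiples %s", fit.lam, sig)
    return summary


def _plot_beta(grid: np.ndarray, fit, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.fill_between(grid, fit.band_lower, fit.band_upper, alpha=0.3,
                    label=f"{int(fit.level * 100)}% pointwise band")
    ax.plot(grid, fit.beta_hat, lw=1.5, label=r"$\tilde\beta(s)$")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("order (multiples of cadence)")
    ax.set_ylabel("coefficient function")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_all(cfg: RunConfig, outdir: str | Path) -> dict:
    """simulate -> preprocess -> fit in one call, one seed, one directory."""
    outdir = Path(outdir)
    run_simulate(cfg, outdir)
    run_preprocess(cfg, outdir, outdir)
    return run_fit(cfg, outdir, outdir / "cohort.csv", outdir)
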