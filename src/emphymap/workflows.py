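"""End-to-end orchestration: simulate → mask → metrics → point-process fit →
cohort assembly → regressions → biomarker scan.

A run is driven by a JSON config validated into :class:`RunConfig`; every
stochastic stage derives its generator from the single run seed, every tunable
appears in the manifest, and outputs are content-hashed so a repeated run with
the same config produces an identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .imaging_io import (
    BinaryMask, CTVolume, compute_pct_laa, extract_slice_patterns,
    load_mask, load_volume, make_threshold_mask, save_mask, save_volume,
)
from .cluster_metrics import (
    cluster_size_distribution, compute_join_counts, fit_power_law,
    label_connected_components,
)
from .point_process import (
    ChainSettings, SNCPPriors, aggregate_subject, fit_sncp_slice, summarize_slice,
)
from .synthetic_data import (
    METRIC_NAMES, OUTCOME_NAMES, CohortSpec, SubjectImagingSpec,
    simulate_cohort, simulate_subject,
)
from .association_pipeline import (
    EHP4_METRICS, adjusted_r2_gain, fit_ridge, fit_univariate,
    run_ehp_biomarker_scan, standardize_metrics,
)

logger = logging.getLogger(__name__)

CONNECTIVITY_VOCAB = ("faces", "faces+edges", "faces+edges+corners")
RIDGE_VOCAB = ("hoerl_kennard", "hoerl_kennard_baldwin",
               "kibria_am", "kibria_gm", "kibria_med")


@dataclass(frozen=True)
class RunConfig:
    """Validated full-pipeline configuration; all tunables explicit."""

    seed: int
    outdir: str = "emphymap_run"
    n_subjects: int = 300              # statistical cohort size
    n_imaging_subjects: int = 3        # subjects simulated as CT stacks
    imaging_n_slices: int = 8
    imaging_extent_mm: float = 40.0    # max window semi-axis of simulated lungs
    laa_threshold_hu: float = -950.0
    min_lung_voxels: int = 100
    connectivity: str = "faces"
    power_law_method: str = "discrete"
    power_law_x_min: int = 1
    d_convention: str = "alpha-1"
    mcmc_n_iter: int = 800
    mcmc_burn_in: int = 300
    mcmc_thin: int = 5
    ridge_method: str = "kibria_gm"
    fdr: float = 0.10

    def chain_settings(self) -> ChainSettings:
        return ChainSettings(n_iter=self.mcmc_n_iter, burn_in=self.mcmc_burn_in,
                             thin=self.mcmc_thin)


def validate_config(source) -> RunConfig:
    """Build a :class:`RunConfig` from a dict or JSON file path (strict keys)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = json.load(fh)
    elif isinstance(source, dict):
        data = dict(source)
    else:
        raise TypeError("config source must be a path or a dict")

    known = {f.name: f for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in data:
        raise ValueError("config must provide a seed")
    cfg = RunConfig(**data)
    if cfg.connectivity not in CONNECTIVITY_VOCAB:
        raise ValueError(f"connectivity must be one of {CONNECTIVITY_VOCAB}")
    if cfg.ridge_method not in RIDGE_VOCAB:
        raise ValueError(f"ridge_method must be one of {RIDGE_VOCAB}")
    if not (0 < cfg.fdr < 1):
        raise ValueError("fdr must lie in (0, 1)")
    if cfg.mcmc_burn_in >= cfg.mcmc_n_iter:
        raise ValueError("mcmc_burn_in must be smaller than mcmc_n_iter")
    logger.info("validated config: %s", asdict(cfg))
    return cfg


def config_to_json(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(cfg), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Stage helpers (also used by the CLI subcommands)


def compute_metrics(laa: BinaryMask, lung: BinaryMask, cfg: RunConfig | None = None) -> dict:
    """%LAA, power-law D and NJC for one LAA/lung mask pair (3D)."""
    cfg = cfg or RunConfig(seed=0)
    labels = label_connected_components(laa, connectivity=cfg.connectivity)
    sizes = cluster_size_distribution(labels)
    fit = fit_power_law(sizes, "fixed", cfg.power_law_method,
                        x_min=cfg.power_law_x_min, d_convention=cfg.d_convention)
    joins = compute_join_counts(laa, lung, connectivity=cfg.connectivity)
    return {
        "pct_laa": compute_pct_laa(laa, lung),
        "n_clusters": labels.n_clusters,
        "D": fit.D, "alpha": fit.alpha, "d_convention": fit.d_convention,
        "power_law_degenerate": fit.degenerate,
        "njc": joins.njc,
        "j_ll": joins.j_ll, "j_nl": joins.j_nl, "j_nn": joins.j_nn,
        "connectivity": cfg.connectivity,
    }


def fit_point_process_subject(
    laa: BinaryMask,
    lung: BinaryMask,
    cfg: RunConfig,
    seed: int,
    scalar_metrics: dict | None = None,
    subject_id: str = "subject",
):
    """Per-slice SNCP fits and the slice-averaged subject profile."""
    patterns = extract_slice_patterns(laa, lung, min_lung_voxels=cfg.min_lung_voxels)
    if not patterns:
        raise ValueError("no slice passed the minimum lung-voxel filter")
    seeds = np.random.SeedSequence(seed).generate_state(len(patterns)) % (2**31)
    summaries = []
    for pattern, s in zip(patterns, seeds):
        post = fit_sncp_slice(pattern, chain=cfg.chain_settings(), seed=int(s))
        summaries.append(summarize_slice(post, pattern))
    scalars = scalar_metrics or {}
    return aggregate_subject(summaries, subject_id=subject_id,
                             pct_laa=scalars.get("pct_laa", np.nan),
                             D=scalars.get("D", np.nan),
                             njc=scalars.get("njc", np.nan),
                             pct_gt=scalars.get("pct_gt", np.nan))


def regression_tables(cohort: pd.DataFrame, cfg: RunConfig):
    """Univariate, ridge, and adjusted-R²-gain tables for all outcomes."""
    work = standardize_metrics(cohort, METRIC_NAMES)
    outcomes = [o for o in OUTCOME_NAMES if o in cohort.columns]

    uni_rows = []
    for outcome in outcomes:
        for metric in METRIC_NAMES:
            r = fit_univariate(work, outcome, f"{metric}_z")
            uni_rows.append({"outcome": outcome, "metric": metric,
                             "coefficient": r.coefficient, "std_error": r.std_error,
                             "p_value": r.p_value, "r_squared": r.r_squared, "n": r.n})
    univariate = pd.DataFrame(uni_rows)

    ridge_metrics = ["pct_laa_z", "D_z", "njc_z", "acs_z"]
    ridge_rows, gain_rows = [], []
    for outcome in outcomes:
        rf = fit_ridge(work, outcome, ridge_metrics, k_method=cfg.ridge_method)
        for t in rf.terms[: len(ridge_metrics)]:
            ridge_rows.append({"outcome": outcome, "term": t.term, "k": rf.k,
                               "coefficient": t.coefficient, "std_error": t.std_error,
                               "p_value": t.p_value})
        full, red = adjusted_r2_gain(work, outcome, ridge_metrics,
                                     ["pct_laa_z", "D_z", "njc_z"],
                                     k_method=cfg.ridge_method)
        gain_rows.append({"outcome": outcome, "adj_r2_reduced": red,
                          "adj_r2_full": full, "gain": full - red})
    return univariate, pd.DataFrame(ridge_rows), pd.DataFrame(gain_rows)


# ---------------------------------------------------------------------------
# The full pipeline


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in dependency order and return the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_seq = np.random.SeedSequence(cfg.seed)
    cohort_seed, imaging_seed, pp_seed = (int(s) for s in root_seq.generate_state(3) % (2**31))

    artifacts: dict[str, str] = {}

    def emit(name: str, path: Path):
        artifacts[name] = str(path.relative_to(outdir))

    # stage: simulate statistical cohort
    sim = simulate_cohort(CohortSpec(n_subjects=cfg.n_subjects), seed=cohort_seed)
    cohort_csv = outdir / "cohort.csv"
    sim.cohort.to_csv(cohort_csv, index=False)
    emit("cohort_csv", cohort_csv)
    markers_csv = outdir / "biomarkers.csv"
    sim.biomarkers.to_csv(markers_csv, index=False)
    emit("biomarkers_csv", markers_csv)
    lloq_csv = outdir / "lloq.csv"
    sim.lloq.to_frame().to_csv(lloq_csv)
    emit("lloq_csv", lloq_csv)

    # stage: simulate imaging subjects, mask, metrics, point-process fits
    img_seeds = np.random.SeedSequence(imaging_seed).generate_state(
        cfg.n_imaging_subjects) % (2**31)
    pp_seeds = np.random.SeedSequence(pp_seed).generate_state(
        cfg.n_imaging_subjects) % (2**31)
    metric_rows = []
    spec = SubjectImagingSpec(
        n_slices=cfg.imaging_n_slices,
        max_semi_axes_mm=(cfg.imaging_extent_mm, cfg.imaging_extent_mm))
    for i in range(cfg.n_imaging_subjects):
        sid = f"IMG{i:03d}"
        volume, lung, laa_true, _ = simulate_subject(spec, seed=int(img_seeds[i]))
        vol_path = outdir / f"{sid}_ct.nii.gz"
        lung_path = outdir / f"{sid}_lung.nii.gz"
        save_volume(vol_path, volume)
        save_mask(lung_path, lung)
        emit(f"{sid}_ct", vol_path)
        emit(f"{sid}_lung", lung_path)

        laa = make_threshold_mask(volume, lung, cfg.laa_threshold_hu)
        laa_path = outdir / f"{sid}_laa.nii.gz"
        save_mask(laa_path, laa)
        emit(f"{sid}_laa", laa_path)

        scalars = compute_metrics(laa, lung, cfg)
        profile = fit_point_process_subject(laa, lung, cfg, seed=int(pp_seeds[i]),
                                            scalar_metrics=scalars, subject_id=sid)
        row = profile.to_dict()
        row.update({"alpha": scalars["alpha"], "n_clusters": scalars["n_clusters"]})
        metric_rows.append(row)

    metrics_tsv = outdir / "imaging_metrics.tsv"
    pd.DataFrame(metric_rows).to_csv(metrics_tsv, sep="\t", index=False)
    emit("imaging_metrics_tsv", metrics_tsv)

    # stage: regressions on the statistical cohort
    univariate, ridge, gains = regression_tables(sim.cohort, cfg)
    for name, frame in (("univariate", univariate), ("ridge", ridge),
                        ("adjusted_r2_gain", gains)):
        path = outdir / f"regression_{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        emit(f"regression_{name}_tsv", path)

    # stage: biomarker scan
    scan = run_ehp_biomarker_scan(sim.cohort, sim.biomarkers, sim.lloq, fdr=cfg.fdr)
    scan_tsv = outdir / "biomarker_scan.tsv"
    scan.table.to_csv(scan_tsv, sep="\t")
    emit("biomarker_scan_tsv", scan_tsv)

    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "seeds": {"root": cfg.seed, "cohort": cohort_seed,
                  "imaging": imaging_seed, "point_process": pp_seed},
        "artifacts": {name: {"path": rel, "sha256": _sha256(outdir / rel)}
                      for name, rel in artifacts.items()},
        "summary": {
            "n_subjects": cfg.n_subjects,
            "n_imaging_subjects": cfg.n_imaging_subjects,
            "ehp2_discoveries": scan.n_ehp2_discoveries,
            "ehp4_discoveries": scan.n_ehp4_discoveries,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
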