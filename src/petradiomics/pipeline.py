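"""End-to-end orchestration: phantoms -> segmentation -> features -> selection
-> survival models -> report.

Stages communicate only through files (NIfTI volumes and masks, CSV tables,
JSON settings), so each stage can be run, inspected and replaced
independently.  A single global seed deterministically derives every stage
seed, and every CSV carries a provenance comment line with the package
version and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import FeatureConfig, FEATURE_NAMES, extract_all
from .segmentation import apply_volume_filter, segment_isocontour
from .selection import correlation_report, stability_select
from .survival import (compare_cindex, cox_fit, crossvalidated_cindex,
                       km_median_split)
from .synthetic import CohortSpec, PhantomSpec, generate_cohort, generate_phantom
from .volume import ImageVolume, VOIMask

__all__ = ["RunConfig", "RunReport", "run_pipeline", "make_report"]

logger = logging.getLogger(__name__)

CLINICAL_COVARIATES = ["gender", "age", "stage", "site_group", "cht"]


@dataclass
class RunConfig:
    """Settings of one pipeline run; serialized verbatim for provenance."""

    n_subjects: int = 40
    seed: int = 0
    # phantom synthesis: per-subject border sigma drawn uniform in this range,
    # so lesions span the sharp-to-Gaussian phenotype continuum
    border_sigma_range_mm: tuple[float, float] = (0.5, 4.0)
    tumor_radius_range_mm: tuple[float, float] = (9.0, 15.0)
    peak_suv_range: tuple[float, float] = (6.0, 15.0)
    noise_sd: float = 0.5
    # segmentation / features
    isocontour_fraction: float = 0.40
    n_bins: int = 64
    volume_threshold_ml: float = 2.6
    # cohort: hazard driven by the named image features (log HR per sd)
    log_hr_per_feature: dict[str, float] = field(
        default_factory=lambda: {"LILRE": -1.0})
    censoring_rate: float = 0.3
    baseline_hazard: float = 0.02
    # selection / survival
    stability_runs: int = 1000
    stability_threshold: float = 0.5
    cv_folds: int = 10
    n_boot: int = 2000
    imaging_candidates: tuple[str, ...] = (
        "run_percentage", "LILRE", "coarseness", "code_similarity",
        "LILZE", "SUL_peak", "GLCM_homogeneity", "GLCM_contrast")
    forced_clinical: tuple[str, ...] = ("age", "stage")

    def __post_init__(self) -> None:
        if not 0 < self.isocontour_fraction < 1:
            raise ValueError("isocontour fraction must be in (0, 1)")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        if self.volume_threshold_ml < 0:
            raise ValueError("volume threshold must be nonnegative")
        if self.stability_runs < 1 or self.cv_folds < 2:
            raise ValueError("invalid selection settings")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        for k in ("border_sigma_range_mm", "tumor_radius_range_mm",
                  "peak_suv_range", "imaging_candidates", "forced_clinical"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance_line(config: RunConfig) -> str:
    return f"# petradiomics v{__version__} config={config.config_hash} seed={config.seed}"


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line(config) + "\n")
        df.to_csv(fh, index=index)


def read_output_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the provenance comment line."""
    return pd.read_csv(path, comment="#", **kwargs)


@dataclass
class RunReport:
    """Paths and headline quantities of a completed run."""

    outdir: Path
    n_subjects: int
    n_excluded: int
    excluded_volumes_ml: list[float]
    selected_features: list[str]
    selection_frequencies: dict[str, float]
    cindex_clinical: float
    cindex_imaging: float
    cindex_delta: float
    cindex_p: float
    km_logrank_p: float
    km_feature: str | None


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunReport:
    """Execute every stage and write all artifacts under ``outdir``.

    Outputs: per-subject volumes and masks (NIfTI), ``features.csv`` with a
    JSON sidecar of extraction settings, ``cohort.csv``,
    ``selection_frequencies.csv`` + ``selection.json``, a univariate Cox
    table, clinical-only and clinical+imaging multivariate tables, a c-index
    comparison and Kaplan-Meier split summary, and ``report.md``.  Identical
    config and seed give identical CSV outputs.
    """
    out = Path(outdir)
    for sub in ("volumes", "masks"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    phantom_seed, cohort_seed, select_seed, surv_seed, misc_seed = \
        _stage_seeds(config.seed, 5)
    rng = np.random.default_rng(phantom_seed)

    # ---- stage 1: synthesis ------------------------------------------------
    specs = []
    for i in range(config.n_subjects):
        spec = PhantomSpec(
            tumor_radius_mm=float(rng.uniform(*config.tumor_radius_range_mm)),
            peak_suv=float(rng.uniform(*config.peak_suv_range)),
            border_sigma_mm=float(rng.uniform(*config.border_sigma_range_mm)),
            noise_sd=config.noise_sd,
            seed=int(rng.integers(0, 2**31)),
        )
        specs.append(spec)
        vol = generate_phantom(spec)
        vol.to_nifti(str(out / "volumes" / f"S{i:04d}.nii.gz"))

    # ---- stage 2: segmentation + volume filter -----------------------------
    masks: list[VOIMask] = []
    for i in range(config.n_subjects):
        try:
            vol = ImageVolume.from_nifti(str(out / "volumes" / f"S{i:04d}.nii.gz"))
            mask = segment_isocontour(vol, fraction=config.isocontour_fraction)
        except Exception as exc:
            raise RuntimeError(f"segmentation failed for subject S{i:04d}: {exc}") from exc
        mask.to_nifti(str(out / "masks" / f"S{i:04d}.nii.gz"))
        masks.append(mask)
    filt = apply_volume_filter(masks, threshold_ml=config.volume_threshold_ml)
    if not filt.retained:
        raise RuntimeError(
            f"empty cohort: all {config.n_subjects} subjects fell below the "
            f"{config.volume_threshold_ml} ml volume threshold")

    # ---- stage 3: features -------------------------------------------------
    fc = FeatureConfig(n_bins=config.n_bins)
    rows = []
    for i in filt.retained:
        vol = ImageVolume.from_nifti(str(out / "volumes" / f"S{i:04d}.nii.gz"))
        try:
            feats = extract_all(vol, masks[i], config=fc)
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed for subject S{i:04d}: {exc}") from exc
        feats["subject_id"] = f"S{i:04d}"
        rows.append(feats)
    features = pd.DataFrame(rows).set_index("subject_id")[list(FEATURE_NAMES)]
    _write_csv(features.reset_index(), out / "features.csv", config)
    sidecar = {"version": __version__, **fc.to_dict(),
               "n_directions": 13, "isocontour_fraction": config.isocontour_fraction,
               "volume_threshold_ml": config.volume_threshold_ml,
               "config_hash": config.config_hash}
    (out / "features.json").write_text(json.dumps(sidecar, indent=2))

    # ---- stage 4: cohort ---------------------------------------------------
    cspec = CohortSpec(n_subjects=len(filt.retained),
                       censoring_rate=config.censoring_rate,
                       baseline_hazard=config.baseline_hazard,
                       log_hr_per_feature=dict(config.log_hr_per_feature),
                       seed=cohort_seed)
    feature_cols = features.drop(columns=["SUL_peak"], errors="ignore") \
        if features["SUL_peak"].isna().all() else features
    cohort = generate_cohort(cspec, feature_cols.reset_index(drop=True))
    # SUL peak needs the cohort's anthropometrics: recompute it now
    if "SUL_peak" not in cohort.columns or cohort["SUL_peak"].isna().all():
        from .features import sul_peak
        suls = []
        for row_i, i in enumerate(filt.retained):
            vol = ImageVolume.from_nifti(str(out / "volumes" / f"S{i:04d}.nii.gz"))
            suls.append(sul_peak(vol, masks[i],
                                 weight_kg=cohort.loc[row_i, "weight_kg"],
                                 height_cm=cohort.loc[row_i, "height_cm"],
                                 sex=cohort.loc[row_i, "gender"]))
        cohort["SUL_peak"] = suls
    _write_csv(cohort, out / "cohort.csv", config)

    # ---- stage 5: stability selection --------------------------------------
    candidates = [c for c in config.imaging_candidates if c in cohort.columns
                  and cohort[c].notna().all()]
    stab = stability_select(cohort[candidates], cohort["time_months"],
                            cohort["event"], n_runs=config.stability_runs,
                            threshold=config.stability_threshold,
                            seed=select_seed, cv_folds=config.cv_folds)
    _write_csv(stab.to_frame().rename_axis("feature").reset_index(),
               out / "selection_frequencies.csv", config)
    (out / "selection.json").write_text(json.dumps({
        "selected": stab.selected, "n_runs": stab.n_runs,
        "threshold": stab.threshold, "seed": stab.seed}, indent=2))
    corr = correlation_report(cohort[candidates], stab.selected,
                              clinical=cohort[["age"]])
    _write_csv(corr, out / "correlations.csv", config)

    # ---- stage 6: survival models ------------------------------------------
    uni_rows = []
    for cov in CLINICAL_COVARIATES:
        try:
            f = cox_fit(cohort, [cov])
            row = f.summary.iloc[0]
            uni_rows.append({"covariate": cov, "p": row["p"], "HR": row["HR"],
                             "HR_lower": row["HR_lower"], "HR_upper": row["HR_upper"]})
        except ValueError as exc:
            logger.warning("univariate fit for %s skipped: %s", cov, exc)
    _write_csv(pd.DataFrame(uni_rows), out / "univariate.csv", config)

    clinical_covs = [c for c in CLINICAL_COVARIATES
                     if cohort[c].nunique() > 1]
    imaging_covs = list(config.forced_clinical) + stab.selected
    imaging_covs = [c for c in dict.fromkeys(imaging_covs) if cohort[c].nunique() > 1]

    fit_clin = cox_fit(cohort, clinical_covs)
    _write_csv(fit_clin.summary.rename_axis("covariate").reset_index(),
               out / "multivariate_clinical.csv", config)
    fit_img = cox_fit(cohort, imaging_covs)
    _write_csv(fit_img.summary.rename_axis("covariate").reset_index(),
               out / "multivariate_imaging.csv", config)

    c_clin, scores_clin = crossvalidated_cindex(
        cohort, clinical_covs, k=config.cv_folds, seed=surv_seed, return_scores=True)
    c_img, scores_img = crossvalidated_cindex(
        cohort, imaging_covs, k=config.cv_folds, seed=surv_seed, return_scores=True)
    comp = compare_cindex(scores_img, scores_clin, cohort["time_months"],
                          cohort["event"], n_boot=config.n_boot, seed=misc_seed)
    comp_df = pd.DataFrame([{
        "cindex_clinical": c_clin, "cindex_imaging": c_img,
        "delta": comp.delta, "ci_lower": comp.ci_lower,
        "ci_upper": comp.ci_upper, "p": comp.p_value}])
    _write_csv(comp_df, out / "cindex_comparison.csv", config)

    # ---- stage 7: Kaplan-Meier split on the lead imaging feature -----------
    km_feature = stab.selected[0] if stab.selected else None
    km_p = np.nan
    if km_feature is not None:
        split = km_median_split(cohort, km_feature)
        km_p = split.logrank_p
        km_df = pd.DataFrame({
            "group": ["low"] * len(split.low.times) + ["high"] * len(split.high.times),
            "time_months": np.concatenate([split.low.times, split.high.times]),
            "survival": np.concatenate([split.low.survival, split.high.survival]),
        })
        _write_csv(km_df, out / "km_median_split.csv", config)
        _plot_km(split, km_feature, out / "km_median_split.png")

    report = RunReport(
        outdir=out, n_subjects=config.n_subjects, n_excluded=filt.n_excluded,
        excluded_volumes_ml=[filt.volumes_ml[i] for i in filt.excluded],
        selected_features=stab.selected,
        selection_frequencies=dict(stab.frequency),
        cindex_clinical=float(c_clin), cindex_imaging=float(c_img),
        cindex_delta=float(comp.delta), cindex_p=float(comp.p_value),
        km_logrank_p=float(km_p), km_feature=km_feature)
    (out / "report.md").write_text(make_report(report))
    return report


def _plot_km(split, feature: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for km, label in ((split.low, f"{feature} <= median"),
                      (split.high, f"{feature} > median")):
        t = np.concatenate([[0.0], np.repeat(km.times, 2)])
        s = np.concatenate([[1.0, 1.0], np.repeat(km.survival, 2)[:-1]]) \
            if km.times.size else np.array([1.0])
        ax.plot(t, s[: len(t)], drawstyle="steps-post", label=label)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    ax.set_title(f"log-rank p = {split.logrank_p:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def make_report(run: RunReport) -> str:
    """Render a human-readable markdown summary of a completed run."""
    lines = [
        "# Pipeline run report",
        "",
        f"Subjects synthesized: {run.n_subjects}",
        f"Excluded for small volume: {run.n_excluded}",
    ]
    for v in run.excluded_volumes_ml:
        lines.append(f"  - excluded tumor volume {v:.2f} ml")
    lines += ["", "## Stability selection", ""]
    if run.selected_features:
        for f in run.selected_features:
            lines.append(f"- {f}: frequency {run.selection_frequencies[f]:.2f}")
    else:
        lines.append("- no imaging feature exceeded the selection threshold")
    lines += [
        "",
        "## Model comparison (cross-validated Harrell c-index)",
        "",
        f"- clinical-only model: c = {run.cindex_clinical:.3f}",
        f"- clinical + imaging model: c = {run.cindex_imaging:.3f}",
        f"- difference: {run.cindex_delta:+.3f} (paired bootstrap p = {run.cindex_p:.3g})",
    ]
    if run.km_feature is not None:
        lines += ["", f"## Kaplan-Meier median split on {run.km_feature}", "",
                  f"- log-rank p = {run.km_logrank_p:.3g}"]
    lines.append("")
    return "\n".join(lines)
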