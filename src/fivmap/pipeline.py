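"""End-to-end pipeline: simulate -> segment -> decompose -> map -> fit -> report.

Orchestrates the stage DAG on a workspace directory, persisting every
intermediate (NIfTI volumes, cohort CSV, Z-map TSV, per-model JSON, report
tables) so stages can also be re-run individually from disk. All randomness
descends from the cohort config's root seed, making re-runs bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import lesion_mapping as lmap
from . import parcellation as parc_mod
from . import outcome_models as om
from .segmentation import clean_mask, segment_mirror_difference
from .synthetic import CohortConfig, generate_cohort
from .volumes import IntensityVolume, LesionMask, Parcellation, load_nifti

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "make_report", "fit_results_frame"]


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    workdir: str | Path = "fivmap_run"
    segmentation_threshold: float = 0.20
    min_cluster_voxels: int = 5
    use_truth_masks: bool = False
    relevance_source: str = "external_table"  # or 'derived_from_zmap'
    min_group: int = lmap.MIN_GROUP_DEFAULT
    adjusted: str = "both"  # 'no' | 'yes' | 'both'
    write_volumes: bool = True

    def __post_init__(self) -> None:
        if self.relevance_source not in ("external_table", "derived_from_zmap"):
            raise ValueError("relevance_source must be 'external_table' or 'derived_from_zmap'")


@dataclass
class ReportBundle:
    """Paper-shaped outputs: model table, per-mRS volume summaries, stacked per-patient volumes."""

    model_table: pd.DataFrame
    volume_by_mrs: pd.DataFrame
    patient_volumes: pd.DataFrame
    delong: dict
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.model_table.to_csv(out / "model_table.tsv", sep="\t", index=False)
        self.volume_by_mrs.to_csv(out / "volume_by_mrs.tsv", sep="\t", index=False)
        self.patient_volumes.to_csv(out / "patient_volumes.tsv", sep="\t", index=False)
        (out / "delong.json").write_text(json.dumps(self.delong, indent=2, sort_keys=True))
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))


def _segment_patients(
    parc: Parcellation,
    intensities,
    lesions,
    config: PipelineConfig,
) -> list[LesionMask]:
    """Produce the analysis masks: segmented from intensities, or the truth masks."""
    if config.use_truth_masks:
        return list(lesions)
    masks = []
    for vol in intensities:
        seg = segment_mirror_difference(vol, threshold=config.segmentation_threshold)
        masks.append(clean_mask(seg, config.min_cluster_voxels))
    return masks


def _occupancy_frame(masks: list[LesionMask], parc: Parcellation, patient_ids) -> pd.DataFrame:
    region_ids = parc.region_ids
    rows = []
    for pid, mask in zip(patient_ids, masks):
        hit = np.unique(parc.labels[mask.values])
        hit = set(int(h) for h in hit if h != 0)
        for rid in region_ids:
            rows.append({"patient_id": pid, "region_id": int(rid), "occupied": rid in hit})
    return pd.DataFrame(rows)


def fit_results_frame(results: dict[str, om.FitResult]) -> pd.DataFrame:
    """Flatten fit results into a Table-2-shaped frame (one row per model x predictor)."""
    base = {k: v for k, v in results.items() if not k.endswith("_adjusted")}
    rows = []
    for name, res in base.items():
        adj = results.get(f"{name}_adjusted")
        for pred in res.spec.predictors:
            est = res.estimate(pred)
            row = {
                "model": name,
                "outcome": res.spec.outcome,
                "predictor": pred,
                "or_per_10mL": est.or_per_10mL,
                "or_ci95_low": est.or_ci95_low,
                "or_ci95_high": est.or_ci95_high,
                "p_value": est.p_value,
                "aic": res.aic,
                "c_statistic": res.c_statistic,
                "n_used": res.n_used,
            }
            if adj is not None:
                adj_est = adj.estimate(pred)
                row.update(
                    {
                        "adj_or_per_10mL": adj_est.or_per_10mL,
                        "adj_or_ci95_low": adj_est.or_ci95_low,
                        "adj_or_ci95_high": adj_est.or_ci95_high,
                    }
                )
            rows.append(row)
    return pd.DataFrame(rows)


def volume_summaries_by_mrs(cohort: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of each relevance-class volume per mRS level."""
    rows = []
    for mrs, grp in cohort.groupby("mrs_90d", sort=True):
        for col in ("fiv_low", "fiv_mod", "fiv_high", "fiv_total"):
            q1, med, q3 = np.percentile(grp[col], [25, 50, 75])
            rows.append(
                {
                    "mrs_90d": int(mrs),
                    "volume_class": col,
                    "n": len(grp),
                    "median_mL": med,
                    "iqr_low_mL": q1,
                    "iqr_high_mL": q3,
                }
            )
    return pd.DataFrame(rows)


def make_report(
    results: dict[str, om.FitResult], cohort: pd.DataFrame, manifest: dict | None = None
) -> ReportBundle:
    """Assemble the paper-shaped report from fitted models and the cohort table.

    The per-patient stacked-volume table is sorted by total volume ascending
    (each row one subject), and the DeLong comparison contrasts the
    total-volume and high-relevance-volume binary models when both exist.
    """
    if not results:
        raise ValueError("no fitted models to report")
    model_table = fit_results_frame(results)
    volume_by_mrs = volume_summaries_by_mrs(cohort)
    patient_volumes = (
        cohort[["patient_id", "fiv_high", "fiv_mod", "fiv_low", "fiv_total", "mrs_90d"]]
        .sort_values("fiv_total", kind="mergesort")
        .reset_index(drop=True)
    )
    delong: dict = {}
    m1, m2 = results.get("model_1"), results.get("model_2")
    if m1 is not None and m2 is not None:
        labels = om.favorable(cohort["mrs_90d"])
        delong = om.delong_compare(m1.scores, m2.scores, labels)
        delong = {k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v)) for k, v in delong.items()}
        delong["comparison"] = "model_1 (total FIV) vs model_2 (high mRS-relevant FIV)"
    return ReportBundle(
        model_table=model_table,
        volume_by_mrs=volume_by_mrs,
        patient_volumes=patient_volumes,
        delong=delong,
        manifest=manifest or {},
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full pipeline in the workspace; returns the report bundle."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate: n=%d", config.cohort.n_patients)
    sim = generate_cohort(config.cohort, out_dir=workdir, write_volumes=False)
    parc: Parcellation = sim["parcellation"]
    cohort: pd.DataFrame = sim["cohort"]
    if config.write_volumes:
        # persist volumes for stage isolation / re-runs
        from .volumes import save_nifti

        for pid, vol, les in zip(cohort["patient_id"], sim["intensities"], sim["lesions"]):
            save_nifti(workdir / f"{pid}_dwi.nii.gz", vol.values, parc.spacing)
            save_nifti(workdir / f"{pid}_truth_mask.nii.gz", les.values, parc.spacing)

    logger.info("stage segment (threshold=%.2f)", config.segmentation_threshold)
    masks = _segment_patients(parc, sim["intensities"], sim["lesions"], config)

    logger.info("stage map: region z-map")
    occupancy = _occupancy_frame(masks, parc, cohort["patient_id"])
    occupancy.to_csv(workdir / "occupancy.csv", index=False)
    zmap = lmap.region_zmap(
        occupancy, cohort[["patient_id", "mrs_90d"]], min_group=config.min_group
    )
    zmap.to_tsv(workdir / "zmap.tsv")

    if config.relevance_source == "derived_from_zmap":
        table = lmap.classify_relevance(zmap)
        parc_mod.save_relevance_table(table, workdir / "relevance_derived.tsv")
    else:
        table = sim["relevance_table"]

    logger.info("stage decompose")
    sub_rows = []
    for pid, mask in zip(cohort["patient_id"], masks):
        sub = parc_mod.decompose_volumes(mask, parc, table)
        sub_rows.append({"patient_id": pid, **sub.as_dict()})
    analysis = pd.DataFrame(sub_rows).merge(
        cohort.drop(columns=["fiv_total", "fiv_high", "fiv_mod", "fiv_low", "fiv_unclassified"]),
        on="patient_id",
    )
    analysis.to_csv(workdir / "analysis_cohort.csv", index=False)

    logger.info("stage fit: model roster (adjusted=%s)", config.adjusted)
    results = om.fit_roster(analysis, adjusted=config.adjusted)
    models_dir = workdir / "models"
    models_dir.mkdir(exist_ok=True)
    for name, res in results.items():
        payload = {
            "spec": {
                "outcome": res.spec.outcome,
                "predictors": list(res.spec.predictors),
                "adjusted": res.spec.adjusted,
            },
            "estimates": {k: vars(v) for k, v in res.estimates.items()},
            "loglik": res.loglik,
            "aic": res.aic,
            "c_statistic": res.c_statistic,
            "n_used": res.n_used,
            "n_excluded": res.n_excluded,
        }
        (models_dir / f"{name}.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    logger.info("stage report")
    manifest = dict(sim["manifest"])
    manifest.update(
        {
            "segmentation_threshold": config.segmentation_threshold,
            "min_cluster_voxels": config.min_cluster_voxels,
            "use_truth_masks": config.use_truth_masks,
            "relevance_source": config.relevance_source,
        }
    )
    bundle = make_report(results, analysis, manifest)
    bundle.write(workdir / "report")
    return bundle
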