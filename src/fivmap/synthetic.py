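"""Synthetic atlas-space stroke cohorts for exercising the analysis end to end.

Real follow-up DWI of large-vessel-occlusion stroke cohorts is not publicly
available, so this module generates stand-ins with the statistical structure
the downstream analysis assumes:

* a left/right mirror-symmetric "brain" (an ellipsoid) partitioned into 66
  homologous regions (33 per hemisphere), organised in three radial bands
  around a deep per-hemisphere anchor — a contiguous deep core of high
  mRS-relevance regions, a surrounding moderate shell, and a peripheral
  cortex-like low shell;
* lesions grown as 6-connected random flood fills from a seed voxel inside a
  high-relevance region, strictly preferring high- over moderate- over
  low-relevance frontier voxels. Because the relevance bands are radially
  contiguous (band thickness far exceeds one voxel step), a connected lesion
  cannot reach the low band without containing moderate-band tissue: small
  lesions occupy only high-relevance regions and occupancy progresses
  high -> moderate -> low as total volume grows, by construction;
* trace-DWI-like intensities: uniform baseline inside the brain with
  multiplicative noise (mirror-symmetric by default, so that noise alone
  never crosses the left/right asymmetry threshold; an independent-noise
  mode exists for robustness checks), with lesioned voxels elevated by a
  configurable contrast relative to their mirrored counterparts;
* ordinal 90-day mRS outcomes drawn from a proportional-odds latent model
  logit P(mRS <= k) = alpha_k + beta_high V_high + beta_mod V_mod +
  beta_low V_low + gamma . covariates, with negative beta meaning larger
  volume lowers the odds of a good outcome; plus the standard adjustment
  covariates (age, sex, diabetes, atrial fibrillation, prior stroke or
  pre-stroke disability, treatment allocation, occlusion site,
  onset-to-treatment time, collateral score).

All randomness flows from a single root seed through named per-stage
substreams, so identical configurations reproduce bit-identical cohorts.
"""

from __future__ import annotations

import hashlib
import heapq
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import parcellation as parc_mod
from .volumes import IntensityVolume, LesionMask, Parcellation, save_nifti, voxel_volume_mL

__all__ = [
    "CohortConfig",
    "InvalidConfigError",
    "InfeasibleTargetError",
    "generate_parcellation",
    "generate_lesion",
    "render_intensity",
    "draw_covariates",
    "latent_index",
    "simulate_outcomes",
    "generate_cohort",
]


class InvalidConfigError(ValueError):
    pass


class InfeasibleTargetError(ValueError):
    pass


#: default ordinal cut-points alpha_0..alpha_5, calibrated once by simulation
#: under the default generator so that the marginal favorable-outcome
#: (mRS <= 2) rate is ~53%; see docs/methods.md.
DEFAULT_CUTPOINTS = (-0.698, 0.889, 2.090, 2.858, 3.589, 3.976)

DEFAULT_GAMMA = {"age": -0.02, "treatment_allocation": 0.6, "collateral_score": 0.25}

#: Cohort-table prevalence anchors for the covariate generators.
COVARIATE_DEFAULTS = {
    "age_mean": 66.0,
    "age_sd": 14.0,
    "age_range": (18.0, 95.0),
    "p_female": 0.51,
    "p_diabetes": 0.16,
    "p_atrial_fibrillation": 0.44,
    "p_prior_stroke_or_prestroke_mrs_gt0": 0.19,
    "p_evt": 0.52,
    "p_occlusion": {"ICA-T": 0.22, "M1": 0.72, "M2": 0.06},
    "onset_to_treatment_mean": 195.0,
    "onset_to_treatment_sd": 97.6,
    "onset_to_treatment_range": (30.0, 720.0),
    "p_collateral": (0.10, 0.25, 0.40, 0.25),
}


@dataclass
class CohortConfig:
    """Everything needed to generate one synthetic cohort.

    Volumes are in mL; ``contrast`` and ``noise_sd`` are fractions of the
    baseline intensity; betas are per mL on the latent proportional-odds
    scale (negative = harmful); ``cutpoints`` are the six ordinal
    intercepts alpha_0..alpha_5 and must be strictly increasing.
    """

    n_patients: int = 252
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_regions: int = 66
    #: cumulative hemisphere volume fractions at the high/moderate and
    #: moderate/low band edges: the deep high-relevance core is small (as the
    #: internal capsule / corona radiata / lentiform complex is), the
    #: cortex-like low band large.
    band_fractions: tuple[float, float] = (0.10, 0.30)
    lesion_volume_log_mean: float = 3.9  # log-mL; median exp(3.9) ~ 49 mL
    lesion_volume_log_sd: float = 1.1
    contrast: float = 0.30
    noise_sd: float = 0.05
    #: surface roughness of grown lesions: random jitter (mm) added to the
    #: distance-from-seed growth priority; 0 gives near-spherical lesions,
    #: large values approach an unbiased Eden growth with a ragged surface.
    lesion_roughness_mm: float = 4.0
    symmetric_noise: bool = True
    beta_high: float = -0.05
    beta_mod: float = 0.0
    beta_low: float = 0.0
    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS
    gamma: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    covariates: Mapping[str, object] = field(default_factory=lambda: dict(COVARIATE_DEFAULTS))
    relevance_override: Mapping[int, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidConfigError("n_patients must be positive")
        if any(d < 32 for d in self.grid_shape):
            raise InvalidConfigError("grid dims must be >= 32 per axis")
        if self.grid_shape[0] % 2 != 0:
            raise InvalidConfigError("extent along the mirror axis (axis 0) must be even")
        if self.n_regions < 6 or self.n_regions % 2 != 0:
            raise InvalidConfigError("n_regions must be an even number >= 6")
        if self.lesion_volume_log_sd < 0 or self.noise_sd < 0:
            raise InvalidConfigError("dispersion parameters must be nonnegative")
        if self.contrast <= -1:
            raise InvalidConfigError("contrast must exceed -1")
        if len(self.cutpoints) != 6 or not np.all(np.diff(self.cutpoints) > 0):
            raise InvalidConfigError("cutpoints must be 6 strictly increasing values")
        f1, f2 = self.band_fractions
        if not 0 < f1 < f2 < 1:
            raise InvalidConfigError("band_fractions must satisfy 0 < f1 < f2 < 1")

    @property
    def voxel_mL(self) -> float:
        return voxel_volume_mL(self.voxel_spacing)

    def rng(self, stage: str) -> np.random.Generator:
        """Named deterministic substream of the root seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return np.random.default_rng(int.from_bytes(h[:8], "little"))

    def to_json(self) -> str:
        d = asdict(self)
        d["gamma"] = dict(self.gamma)
        d["covariates"] = dict(self.covariates)
        if d["covariates"].get("p_occlusion"):
            d["covariates"]["p_occlusion"] = dict(d["covariates"]["p_occlusion"])
        return json.dumps(d, sort_keys=True, default=list)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        d = json.loads(text)
        for key in ("grid_shape", "voxel_spacing", "cutpoints", "band_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        if "relevance_override" in d and d["relevance_override"] is not None:
            d["relevance_override"] = {int(k): v for k, v in d["relevance_override"].items()}
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# parcellation geometry
# ---------------------------------------------------------------------------


def _brain_mask(config: CohortConfig) -> np.ndarray:
    """Mirror-symmetric ellipsoidal brain mask (semi-axes 45% of grid extent)."""
    shape = config.grid_shape
    sp = config.voxel_spacing
    coords = [(np.arange(e) - (e - 1) / 2.0) * d for e, d in zip(shape, sp)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    semi = [0.45 * e * d for e, d in zip(shape, sp)]
    return (xx / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (zz / semi[2]) ** 2 <= 1.0


def generate_parcellation(config: CohortConfig) -> Parcellation:
    """Build the symmetric banded parcellation.

    The left hemisphere (indices below the mid-plane of axis 0) is split
    into three radial distance bands of roughly equal voxel count around a
    deep anchor, each band partitioned into Voronoi cells seeded at random
    band voxels. Band order encodes relevance: innermost = high, middle =
    moderate, outer = low. The right hemisphere is the mirror image with
    region ids offset by half the region count, so homologous regions have
    identical voxel counts by construction.
    """
    rng = config.rng("parcellation")
    shape = config.grid_shape
    sp = config.voxel_spacing
    brain = _brain_mask(config)
    half = shape[0] // 2
    left = brain.copy()
    left[half:, :, :] = False
    n_left = int(left.sum())
    n_per_hemi = config.n_regions // 2
    if n_per_hemi > n_left:
        raise InvalidConfigError(
            f"{config.n_regions} regions requested but hemisphere has only {n_left} voxels"
        )

    idx = np.argwhere(left)
    pos_mm = idx * np.asarray(sp)
    # deep anchor: near the mid-plane, centred in the other two axes
    anchor = np.array(
        [
            (half - 1 - shape[0] / 8.0) * sp[0],
            (shape[1] - 1) / 2.0 * sp[1],
            (shape[2] - 1) / 2.0 * sp[2],
        ]
    )
    dist = np.linalg.norm(pos_mm - anchor, axis=1)
    f1, f2 = config.band_fractions
    r1, r2 = np.percentile(dist, [100 * f1, 100 * f2])
    band = np.digitize(dist, [r1, r2])  # 0 deep/high, 1 moderate, 2 low

    counts = [n_per_hemi // 3 + (1 if b < n_per_hemi % 3 else 0) for b in range(3)]
    labels = np.zeros(shape, dtype=np.int32)
    next_id = 1
    band_names = {0: "high", 1: "moderate", 2: "low"}
    rows = []
    for b in range(3):
        sel = band == b
        vox = idx[sel]
        n_seeds = counts[b]
        if n_seeds > len(vox):
            raise InvalidConfigError(f"band {b} too small for {n_seeds} regions")
        seeds = vox[rng.choice(len(vox), size=n_seeds, replace=False)]
        d2 = ((vox[:, None, :] * sp - seeds[None, :, :] * sp) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        for s in range(n_seeds):
            cell = vox[assign == s]
            labels[cell[:, 0], cell[:, 1], cell[:, 2]] = next_id
            rows.append(
                {
                    "region_id": next_id,
                    "name": f"L_{band_names[b]}_{s + 1:02d}",
                    "hemisphere": "left",
                    "relevance": band_names[b],
                }
            )
            next_id += 1

    # mirror to the right hemisphere with offset ids
    mirrored = np.flip(labels, axis=0)
    right = mirrored > 0
    labels[right] = mirrored[right] + n_per_hemi
    for row in list(rows):
        rows.append(
            {
                "region_id": row["region_id"] + n_per_hemi,
                "name": row["name"].replace("L_", "R_", 1),
                "hemisphere": "right",
                "relevance": row["relevance"],
            }
        )

    regions = pd.DataFrame(rows)
    if config.relevance_override:
        override = {int(k): v for k, v in config.relevance_override.items()}
        regions["relevance"] = [
            override.get(rid, rel) for rid, rel in zip(regions["region_id"], regions["relevance"])
        ]
    return Parcellation(labels=labels, spacing=sp, regions=regions, mirror_axis=0)


# ---------------------------------------------------------------------------
# lesion growth
# ---------------------------------------------------------------------------

_RANK = {"high": 0, "moderate": 1, "low": 2, "unclassified": 3}


def generate_lesion(
    parc: Parcellation,
    target_volume_mL: float,
    seed: int | np.random.Generator,
    roughness_mm: float = 4.0,
) -> LesionMask:
    """Grow a connected lesion of approximately the target volume.

    Region-graded random flood fill (6-connectivity) from a random seed voxel
    inside a high-relevance region of one hemisphere, always consuming the
    best-relevance frontier voxels first (high, then moderate, then low, then
    unclassified). Within a class, voxels closer to the seed are preferred up
    to a random jitter of ``roughness_mm``, producing compact blobs with a
    tunably irregular surface. The achieved volume is within one voxel of the
    target, and the mask never crosses the mid-plane.
    """
    if target_volume_mL < 0:
        raise ValueError("target volume must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vox_mL = voxel_volume_mL(parc.spacing)
    target_vox = int(round(target_volume_mL / vox_mL))
    shape = parc.labels.shape
    mask = np.zeros(shape, dtype=bool)
    if target_vox == 0:
        return LesionMask(mask, parc.spacing)

    rank_of = {rid: _RANK[rel] for rid, rel in parc.relevance_map().items()}
    rank_lut = np.full(int(parc.labels.max()) + 1, _RANK["unclassified"], dtype=np.int8)
    for rid, rk in rank_of.items():
        rank_lut[rid] = rk
    rank_grid = rank_lut[parc.labels]

    half = shape[0] // 2
    hemi = "left" if rng.random() < 0.5 else "right"
    hemi_slice = slice(0, half) if hemi == "left" else slice(half, shape[0])
    allowed = np.zeros(shape, dtype=bool)
    allowed[hemi_slice, :, :] = parc.brain_mask[hemi_slice, :, :]
    budget = int(allowed.sum())
    if target_vox > budget:
        raise InfeasibleTargetError(
            f"target {target_volume_mL:.1f} mL ({target_vox} voxels) exceeds the "
            f"{hemi} hemisphere capacity of {budget * vox_mL:.1f} mL"
        )

    high_vox = np.argwhere(allowed & (rank_grid == 0))
    if len(high_vox) == 0:
        raise InvalidConfigError("no high-relevance tissue to seed the lesion in")
    start = tuple(high_vox[rng.integers(len(high_vox))])

    neighbors = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))
    sp = np.asarray(parc.spacing)

    def priority(vox: tuple[int, int, int]) -> float:
        d = float(np.linalg.norm((np.asarray(vox) - np.asarray(start)) * sp))
        return d + rng.uniform(0.0, roughness_mm)

    heap: list[tuple[int, float, tuple[int, int, int]]] = []
    heapq.heappush(heap, (int(rank_grid[start]), 0.0, start))
    queued = np.zeros(shape, dtype=bool)
    queued[start] = True
    n_added = 0
    while heap and n_added < target_vox:
        _, _, vox = heapq.heappop(heap)
        if mask[vox]:
            continue
        mask[vox] = True
        n_added += 1
        for d in neighbors:
            nb = (vox[0] + d[0], vox[1] + d[1], vox[2] + d[2])
            if (
                0 <= nb[0] < shape[0]
                and 0 <= nb[1] < shape[1]
                and 0 <= nb[2] < shape[2]
                and allowed[nb]
                and not queued[nb]
            ):
                queued[nb] = True
                heapq.heappush(heap, (int(rank_grid[nb]), priority(nb), nb))
    return LesionMask(mask, parc.spacing)


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

BASELINE_INTENSITY = 100.0


def render_intensity(
    parc: Parcellation,
    lesion: LesionMask,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> IntensityVolume:
    """Render a trace-DWI-like intensity volume for one patient.

    Baseline intensity is uniform inside the brain with multiplicative
    Gaussian noise. With ``symmetric_noise`` the noise field is generated on
    one hemisphere and mirrored, so mirrored voxel pairs share their noise
    factor and the only left/right asymmetry is the lesion itself, elevated
    by exactly ``(1 + contrast)`` relative to its mirrored counterpart.
    """
    if lesion.values.shape != parc.labels.shape:
        raise ValueError("lesion grid does not match parcellation grid")
    brain = parc.brain_mask
    if np.any(lesion.values & ~brain):
        raise ValueError("lesion voxels fall outside the brain mask")
    rng = rng if rng is not None else config.rng("intensity")
    shape = parc.labels.shape
    noise = rng.normal(0.0, config.noise_sd, size=shape) if config.noise_sd > 0 else np.zeros(shape)
    if config.symmetric_noise:
        half = shape[0] // 2
        noise[half:, :, :] = np.flip(noise[:half, :, :], axis=0)
    values = np.zeros(shape)
    values[brain] = BASELINE_INTENSITY * np.clip(1.0 + noise[brain], 0.05, None)
    values[lesion.values] *= 1.0 + config.contrast
    return IntensityVolume(values=values, spacing=parc.spacing, brain_mask=brain, mirror_axis=0)


# ---------------------------------------------------------------------------
# covariates and outcomes
# ---------------------------------------------------------------------------


def _trunc_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def draw_covariates(n: int, config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the adjustment covariate set for n patients."""
    rng = rng if rng is not None else config.rng("covariates")
    cv = config.covariates
    age = _trunc_normal(rng, cv["age_mean"], cv["age_sd"], *cv["age_range"], size=n)
    sites = list(cv["p_occlusion"].keys())
    p_sites = np.array(list(cv["p_occlusion"].values()), dtype=float)
    p_sites = p_sites / p_sites.sum()
    return pd.DataFrame(
        {
            "age": np.round(age, 1),
            "sex": rng.binomial(1, cv["p_female"], n),  # 1 = female
            "diabetes": rng.binomial(1, cv["p_diabetes"], n),
            "atrial_fibrillation": rng.binomial(1, cv["p_atrial_fibrillation"], n),
            "prior_stroke_or_prestroke_mrs_gt0": rng.binomial(
                1, cv["p_prior_stroke_or_prestroke_mrs_gt0"], n
            ),
            "treatment_allocation": np.where(rng.random(n) < cv["p_evt"], "EVT", "control"),
            "occlusion_site": rng.choice(sites, size=n, p=p_sites),
            "onset_to_treatment_min": np.round(
                _trunc_normal(
                    rng,
                    cv["onset_to_treatment_mean"],
                    cv["onset_to_treatment_sd"],
                    *cv["onset_to_treatment_range"],
                    size=n,
                ),
                0,
            ),
            "collateral_score": rng.choice(4, size=n, p=np.asarray(cv["p_collateral"], dtype=float)),
        }
    )


def latent_index(records: pd.DataFrame, config: CohortConfig) -> np.ndarray:
    """Latent linear predictor eta (favorable direction) for each patient.

    Continuous covariates enter centred at their generator means so the
    cut-points control the marginal mRS distribution of an average patient.
    """
    g = dict(config.gamma)
    cv = config.covariates
    eta = (
        config.beta_high * records["fiv_high"].to_numpy(dtype=float)
        + config.beta_mod * records["fiv_mod"].to_numpy(dtype=float)
        + config.beta_low * records["fiv_low"].to_numpy(dtype=float)
    )
    if g.get("age"):
        eta = eta + g["age"] * (records["age"].to_numpy(dtype=float) - cv["age_mean"])
    if g.get("treatment_allocation"):
        evt = (records["treatment_allocation"] == "EVT").to_numpy(dtype=float)
        eta = eta + g["treatment_allocation"] * (evt - cv["p_evt"])
    if g.get("collateral_score"):
        cs = records["collateral_score"].to_numpy(dtype=float)
        mean_cs = float(np.dot(np.arange(4), np.asarray(cv["p_collateral"], dtype=float)))
        eta = eta + g["collateral_score"] * (cs - mean_cs)
    return eta


def simulate_outcomes(
    records: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw 90-day mRS from the proportional-odds latent model.

    P(mRS <= k) = logistic(alpha_k + eta) with eta from :func:`latent_index`;
    outcomes are sampled by inverting the cumulative distribution with one
    uniform draw per patient. Returns a copy with ``mrs_90d`` filled.
    """
    alphas = np.asarray(config.cutpoints, dtype=float)
    if not np.all(np.diff(alphas) > 0):
        raise InvalidConfigError("cutpoints must be strictly increasing")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    elif rng is None:
        rng = config.rng("outcomes")
    eta = latent_index(records, config)
    # cumulative P(mRS <= k), k = 0..5; clip eta to keep expit exact at limits
    cum = 1.0 / (1.0 + np.exp(-(alphas[None, :] + np.clip(eta, -700, 700)[:, None])))
    u = rng.random(len(records))
    mrs = (u[:, None] > cum).sum(axis=1)
    out = records.copy()
    out["mrs_90d"] = mrs.astype(int)
    return out


# ---------------------------------------------------------------------------
# cohort orchestration
# ---------------------------------------------------------------------------


def generate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
    write_volumes: bool = True,
) -> dict:
    """Generate a full synthetic cohort.

    Draws per-patient total-volume targets (log-normal, clipped to 95% of
    one hemisphere), grows the lesions, decomposes them into relevance-class
    sub-volumes, renders intensities, draws covariates and simulates
    outcomes. With ``out_dir`` set, writes per-patient intensity and
    truth-mask NIfTIs, the shared parcellation and relevance table, the
    cohort CSV and a JSON manifest.

    Returns a dict with the parcellation, per-patient lesions/intensities
    (when kept in memory), the cohort DataFrame and the manifest.
    """
    parc = generate_parcellation(config)
    table = parc_mod.RelevanceTable.from_parcellation(parc)
    vol_rng = config.rng("volumes")
    n = config.n_patients

    half_budget_mL = 0.95 * (parc.brain_mask[: config.grid_shape[0] // 2].sum() * config.voxel_mL)
    targets = np.minimum(
        np.exp(vol_rng.normal(config.lesion_volume_log_mean, config.lesion_volume_log_sd, n)),
        half_budget_mL,
    )

    covariates = draw_covariates(n, config)
    lesion_rng = config.rng("lesions")
    intensity_rng = config.rng("intensity")

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        save_nifti(out_path / "parcellation.nii.gz", parc.labels, parc.spacing)
        parc.regions.to_csv(out_path / "regions.tsv", sep="\t", index=False)
        parc_mod.save_relevance_table(
            table,
            out_path / "relevance.tsv",
            names=dict(zip(parc.regions["region_id"], parc.regions["name"])),
        )

    rows = []
    lesions: list[LesionMask] = []
    intensities: list[IntensityVolume] = []
    files = {"intensity": [], "truth_mask": []}
    for i in range(n):
        pid = f"P{i + 1:04d}"
        lesion = generate_lesion(
            parc, float(targets[i]), lesion_rng, roughness_mm=config.lesion_roughness_mm
        )
        sub = parc_mod.decompose_volumes(lesion, parc, table)
        vol = render_intensity(parc, lesion, config, rng=intensity_rng)
        row = {"patient_id": pid, **{k: v for k, v in sub.as_dict().items() if k.startswith("fiv")}}
        rows.append(row)
        if out_path is not None and write_volumes:
            fint = out_path / f"{pid}_dwi.nii.gz"
            fmask = out_path / f"{pid}_truth_mask.nii.gz"
            save_nifti(fint, vol.values, parc.spacing)
            save_nifti(fmask, lesion.values, parc.spacing)
            files["intensity"].append(fint.name)
            files["truth_mask"].append(fmask.name)
        else:
            lesions.append(lesion)
            intensities.append(vol)

    cohort = pd.concat([pd.DataFrame(rows), covariates], axis=1)
    cohort = simulate_outcomes(cohort, config)

    manifest = {
        "n_patients": n,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mirror_axis": 0,
        "grid_shape": list(config.grid_shape),
        "voxel_spacing": list(config.voxel_spacing),
        "files": files,
        "parcellation": "parcellation.nii.gz" if out_path is not None else None,
        "relevance_table": "relevance.tsv" if out_path is not None else None,
        "cohort_csv": "cohort.csv" if out_path is not None else None,
    }
    if out_path is not None:
        cohort.to_csv(out_path / "cohort.csv", index=False)
        (out_path / "config.json").write_text(config.to_json())
        (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "parcellation": parc,
        "relevance_table": table,
        "cohort": cohort,
        "lesions": lesions,
        "intensities": intensities,
        "manifest": manifest,
    }
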