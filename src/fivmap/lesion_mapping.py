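"""Region-level lesion-symptom mapping with the Brunner-Munzel rank test.

For each anatomical region, patients are split into those whose lesion
touches the region ("lesioned") and those spared, and the two groups' 90-day
mRS distributions are compared with the Brunner-Munzel test of stochastic
superiority. The test estimates p_hat = P(X < Y) + 1/2 P(X = Y) where X is
the mRS of a spared patient and Y that of a lesioned patient, so p_hat > 0.5
(positive z) means lesioned patients tend towards worse outcome. The
resulting per-region Z-map is reduced to high/moderate/low mRS-relevance
classes, by z-score tertiles by default or by user-supplied absolute
thresholds.

The test is computed at the region level (66 tests); mid-ranks handle the
heavy ties inherent to a 7-level ordinal outcome, and a Satterthwaite-type
t approximation gives the reference distribution, mapped to the standard
normal scale for the z-score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .parcellation import RelevanceTable

__all__ = [
    "BrunnerMunzelResult",
    "RegionZRecord",
    "RelevanceZMap",
    "brunner_munzel",
    "region_zmap",
    "classify_relevance",
    "tertile_scheme",
    "threshold_scheme",
]

MIN_GROUP_DEFAULT = 5


@dataclass(frozen=True)
class BrunnerMunzelResult:
    """Brunner-Munzel test output.

    ``p_hat`` is the stochastic-superiority estimate P(X<Y) + 1/2 P(X=Y);
    ``statistic`` the studentised rank statistic with ``df`` Satterthwaite
    degrees of freedom; ``z_score`` the statistic mapped onto the standard
    normal scale (quantile transform through the t reference distribution).
    ``degenerate`` flags zero estimated variance (all values tied, or
    complete separation), where the statistic is signed infinity by
    convention.
    """

    p_hat: float
    statistic: float
    df: float
    z_score: float
    p_value: float
    degenerate: bool = False


def brunner_munzel(x, y) -> BrunnerMunzelResult:
    """Brunner-Munzel rank-order test of P(X < Y) + 1/2 P(X = Y) = 1/2.

    Uses pooled mid-ranks: p_hat = (mean pooled rank of y - (n_y+1)/2) / n_x,
    identical to the all-pairs estimate (#{x_i < y_j} + 1/2 #{x_i = y_j}) /
    (n_x n_y). The variance is the rank-based estimator of Brunner & Munzel
    (2000) and the reference distribution a t with Satterthwaite-type df.

    Both samples must have at least 2 observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError(f"both samples need >= 2 observations (got {nx}, {ny})")
    n = nx + ny
    rank_all = stats.rankdata(np.concatenate([x, y]))
    rank_x_pooled, rank_y_pooled = rank_all[:nx], rank_all[nx:]
    rx_bar, ry_bar = rank_x_pooled.mean(), rank_y_pooled.mean()
    p_hat = (ry_bar - (ny + 1) / 2.0) / nx

    # Rank-based variance components (internal ranks remove within-sample ties).
    rank_x_internal = stats.rankdata(x)
    rank_y_internal = stats.rankdata(y)
    sx2 = np.sum((rank_x_pooled - rank_x_internal - rx_bar + (nx + 1) / 2.0) ** 2) / (nx - 1)
    sy2 = np.sum((rank_y_pooled - rank_y_internal - ry_bar + (ny + 1) / 2.0) ** 2) / (ny - 1)
    var_term = nx * sx2 + ny * sy2

    if var_term <= 0:
        sign = math.copysign(1.0, p_hat - 0.5) if p_hat != 0.5 else 0.0
        stat = sign * math.inf if sign else 0.0
        p_value = 1.0 if sign == 0.0 else 0.0
        return BrunnerMunzelResult(
            p_hat=float(p_hat),
            statistic=stat,
            df=math.nan,
            z_score=stat,
            p_value=p_value,
            degenerate=True,
        )

    statistic = nx * ny * (ry_bar - rx_bar) / (n * math.sqrt(var_term))
    df = var_term**2 / ((nx * sx2) ** 2 / (nx - 1) + (ny * sy2) ** 2 / (ny - 1))
    p_value = 2.0 * stats.t.sf(abs(statistic), df)
    # Map the t-distributed statistic onto the standard-normal scale so
    # z-scores from regions with different df are comparable.
    z_score = math.copysign(stats.norm.isf(stats.t.sf(abs(statistic), df)), statistic)
    return BrunnerMunzelResult(
        p_hat=float(p_hat),
        statistic=float(statistic),
        df=float(df),
        z_score=float(z_score),
        p_value=float(p_value),
    )


@dataclass(frozen=True)
class RegionZRecord:
    region_id: int
    n_lesioned: int
    n_spared: int
    p_hat: float
    bm_statistic: float
    df: float
    z_score: float
    p_value: float
    evaluable: bool
    degenerate: bool = False


@dataclass(frozen=True)
class RelevanceZMap:
    records: tuple[RegionZRecord, ...]

    def __iter__(self):
        return iter(self.records)

    def evaluable(self) -> list[RegionZRecord]:
        return [r for r in self.records if r.evaluable]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame().rename(columns={"bm_statistic": "statistic"})
        df[
            [
                "region_id",
                "n_lesioned",
                "n_spared",
                "p_hat",
                "statistic",
                "df",
                "z_score",
                "evaluable",
            ]
        ].to_csv(path, sep="\t", index=False)


def region_zmap(
    occupancy: pd.DataFrame,
    outcomes: pd.DataFrame,
    min_group: int = MIN_GROUP_DEFAULT,
) -> RelevanceZMap:
    """Per-region Brunner-Munzel Z-map of lesion occupancy against mRS.

    Parameters
    ----------
    occupancy : DataFrame
        Columns ``patient_id``, ``region_id``, ``occupied`` (bool/0-1); one
        row per (patient, region).
    outcomes : DataFrame
        Columns ``patient_id``, ``mrs_90d`` (integer 0-6).
    min_group : int
        Minimum patients per arm for a region to be evaluable; regions
        lesioned in (almost) nobody or everybody are flagged, never raised.
    """
    mrs = outcomes.set_index("patient_id")["mrs_90d"]
    if not mrs.between(0, 6).all():
        raise ValueError("mrs_90d must lie in 0..6")
    records = []
    for rid, grp in occupancy.groupby("region_id", sort=True):
        occ = grp.set_index("patient_id")["occupied"].astype(bool)
        common = occ.index.intersection(mrs.index)
        lesioned = mrs.loc[common[occ.loc[common]]]
        spared = mrs.loc[common[~occ.loc[common]]]
        if len(lesioned) < min_group or len(spared) < min_group:
            records.append(
                RegionZRecord(
                    region_id=int(rid),
                    n_lesioned=len(lesioned),
                    n_spared=len(spared),
                    p_hat=math.nan,
                    bm_statistic=math.nan,
                    df=math.nan,
                    z_score=math.nan,
                    p_value=math.nan,
                    evaluable=False,
                )
            )
            continue
        res = brunner_munzel(spared.to_numpy(), lesioned.to_numpy())
        records.append(
            RegionZRecord(
                region_id=int(rid),
                n_lesioned=len(lesioned),
                n_spared=len(spared),
                p_hat=res.p_hat,
                bm_statistic=res.statistic,
                df=res.df,
                z_score=res.z_score,
                p_value=res.p_value,
                evaluable=True,
                degenerate=res.degenerate,
            )
        )
    return RelevanceZMap(tuple(records))


def tertile_scheme(zmap: RelevanceZMap) -> dict[int, str]:
    """Split evaluable regions into high/moderate/low by z-score tertiles.

    Higher z (lesioned patients stochastically worse) means higher
    mRS-relevance. Degenerate complete-separation regions (z = +inf) rank
    above all finite z and are classified high. Ties are broken by ascending
    region id, so equal z-scores assign lower ids to the higher class first.
    """
    ev = zmap.evaluable()
    # sort worst-association last: ascending (z, -region_id) then take thirds from the top
    order = sorted(ev, key=lambda r: (-r.z_score, r.region_id))
    n = len(order)
    n_high = (n + 2) // 3
    n_mod = (n + 1) // 3
    out: dict[int, str] = {}
    for i, rec in enumerate(order):
        if i < n_high:
            out[rec.region_id] = "high"
        elif i < n_high + n_mod:
            out[rec.region_id] = "moderate"
        else:
            out[rec.region_id] = "low"
    return out


def threshold_scheme(z_high: float, z_moderate: float):
    """Absolute z thresholds: z >= z_high -> high, z_moderate <= z < z_high -> moderate, else low."""
    if z_moderate >= z_high:
        raise ValueError("require z_moderate < z_high")

    def scheme(zmap: RelevanceZMap) -> dict[int, str]:
        out = {}
        for rec in zmap.evaluable():
            if rec.z_score >= z_high:
                out[rec.region_id] = "high"
            elif rec.z_score >= z_moderate:
                out[rec.region_id] = "moderate"
            else:
                out[rec.region_id] = "low"
        return out

    return scheme


def classify_relevance(zmap: RelevanceZMap, scheme=tertile_scheme) -> RelevanceTable:
    """Reduce a Z-map to a relevance table; non-evaluable regions -> unclassified."""
    if len(zmap.evaluable()) < 3:
        raise ValueError("need at least 3 evaluable regions to derive relevance classes")
    mapping = dict(scheme(zmap))
    for rec in zmap:
        if not rec.evaluable:
            mapping[rec.region_id] = "unclassified"
    return RelevanceTable(mapping)
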