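"""Decompose a lesion mask into sub-volumes by mRS-relevance class.

Each lesion voxel is attributed to exactly one relevance class (high,
moderate, low, or unclassified) through its region label, so the class
sub-volumes always sum exactly to the total lesion volume in voxel counts.
Lesion voxels outside every labelled region (label 0) fall into the
``unclassified`` bucket rather than being dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .volumes import (
    RELEVANCE_CLASSES,
    AlignmentError,
    LesionMask,
    Parcellation,
    voxel_volume_mL,
)

__all__ = [
    "RelevanceTable",
    "SubvolumeResult",
    "volume_of",
    "decompose_volumes",
    "load_relevance_table",
    "save_relevance_table",
]


@dataclass(frozen=True)
class RelevanceTable:
    """Total mapping region_id -> relevance class."""

    mapping: Mapping[int, str]

    def __post_init__(self) -> None:
        for rid, cls in self.mapping.items():
            if cls not in RELEVANCE_CLASSES:
                raise ValueError(f"unknown relevance class {cls!r} for region {rid}")

    def __getitem__(self, region_id: int) -> str:
        return self.mapping[int(region_id)]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in RELEVANCE_CLASSES}
        for cls in self.mapping.values():
            counts[cls] += 1
        return counts

    @classmethod
    def from_parcellation(cls, parc: Parcellation) -> "RelevanceTable":
        return cls(parc.relevance_map())


@dataclass(frozen=True)
class SubvolumeResult:
    """Relevance-class decomposition of one lesion, in voxel counts and mL.

    ``fiv_total`` counts every lesion voxel;
    ``fiv_high + fiv_mod + fiv_low + fiv_unclassified == fiv_total`` exactly
    in voxel counts. ``classified_total_mL`` excludes the unclassified bucket
    for users who define total FIV over labelled tissue only.
    """

    n_total: int
    n_high: int
    n_mod: int
    n_low: int
    n_unclassified: int
    voxel_mL: float

    @property
    def fiv_total(self) -> float:
        return self.n_total * self.voxel_mL

    @property
    def fiv_high(self) -> float:
        return self.n_high * self.voxel_mL

    @property
    def fiv_mod(self) -> float:
        return self.n_mod * self.voxel_mL

    @property
    def fiv_low(self) -> float:
        return self.n_low * self.voxel_mL

    @property
    def fiv_unclassified(self) -> float:
        return self.n_unclassified * self.voxel_mL

    @property
    def classified_total_mL(self) -> float:
        return (self.n_high + self.n_mod + self.n_low) * self.voxel_mL

    def as_dict(self) -> dict:
        return {
            "fiv_total": self.fiv_total,
            "fiv_high": self.fiv_high,
            "fiv_mod": self.fiv_mod,
            "fiv_low": self.fiv_low,
            "fiv_unclassified": self.fiv_unclassified,
            "classified_total_mL": self.classified_total_mL,
            "n_total": self.n_total,
            "n_high": self.n_high,
            "n_mod": self.n_mod,
            "n_low": self.n_low,
            "n_unclassified": self.n_unclassified,
        }


def volume_of(mask: LesionMask) -> float:
    """Lesion volume in mL: voxel count x voxel volume / 1000."""
    return mask.n_voxels * voxel_volume_mL(mask.spacing)


def decompose_volumes(
    mask: LesionMask, parc: Parcellation, table: RelevanceTable | None = None
) -> SubvolumeResult:
    """Split a lesion into high/moderate/low/unclassified sub-volumes.

    Parameters
    ----------
    mask, parc :
        Must share grid shape and voxel spacing (asserted; inputs are assumed
        already atlas-aligned).
    table :
        Region -> relevance mapping. Defaults to the classes carried by the
        parcellation's own region table.
    """
    if mask.values.shape != parc.labels.shape:
        raise AlignmentError(
            f"lesion grid {mask.values.shape} does not match parcellation grid {parc.labels.shape}"
        )
    if not np.allclose(mask.spacing, parc.spacing):
        raise AlignmentError(f"voxel spacing differs: {mask.spacing} vs {parc.spacing}")
    if table is None:
        table = RelevanceTable.from_parcellation(parc)

    lesion_labels = parc.labels[mask.values]
    counts = np.bincount(lesion_labels, minlength=1)
    n_by_class = {"high": 0, "moderate": 0, "low": 0, "unclassified": int(counts[0])}
    for rid in np.nonzero(counts)[0]:
        if rid == 0:
            continue
        try:
            cls = table[int(rid)]
        except KeyError:
            raise KeyError(f"region id {int(rid)} has no relevance-table entry") from None
        n_by_class[cls] += int(counts[rid])

    return SubvolumeResult(
        n_total=int(lesion_labels.size),
        n_high=n_by_class["high"],
        n_mod=n_by_class["moderate"],
        n_low=n_by_class["low"],
        n_unclassified=n_by_class["unclassified"],
        voxel_mL=voxel_volume_mL(mask.spacing),
    )


def load_relevance_table(source: str | Path) -> RelevanceTable:
    """Read a TSV with header ``region_id<TAB>name<TAB>relevance``.

    Duplicate region ids and unknown relevance labels are rejected.
    """
    df = pd.read_csv(source, sep="\t")
    required = {"region_id", "relevance"}
    if not required <= set(df.columns):
        raise ValueError(f"relevance table must have columns {sorted(required)}")
    dupes = df["region_id"][df["region_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate region id(s) in relevance table: {sorted(set(dupes))}")
    return RelevanceTable(dict(zip(df["region_id"].astype(int), df["relevance"])))


def save_relevance_table(
    table: RelevanceTable, path: str | Path, names: Mapping[int, str] | None = None
) -> None:
    rows = [
        {"region_id": rid, "name": (names or {}).get(rid, f"region_{rid}"), "relevance": cls}
        for rid, cls in sorted(table.mapping.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
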