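"""Region-of-interest aggregation.

The unit of analysis is the surgeon-marked region: an integer-labelled patch
of the joint surface annotated with an ICRS cartilage-injury grade. Grades
< 2 define the healthy control class and grades >= 3 the damaged class;
grade 2 is outside the study's two-class design and is rejected loudly.
Parameter images are reduced to per-region arithmetic pixel means (median
available as an option) and assembled into a flat table with one row per
region, from which per-patient paired vectors are derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import AbsorbanceCube, IndexImage, TWIParams, band_value, twi
from .exceptions import (
    ConsistencyError,
    GradeOutOfScopeError,
    InsufficientDataError,
)

#: stable column order of the region table
REGION_TABLE_COLUMNS = [
    "patient_id",
    "region_id",
    "tissue_class",
    "icrs_grade",
    "n_pixels",
    "mean_a540",
    "mean_a960",
    "mean_twi",
]

INDEX_COLUMNS = {"a540": "mean_a540", "a960": "mean_a960", "twi": "mean_twi"}


def classify_grade(icrs_grade: int) -> str:
    """Map an ICRS grade to the study's two classes.

    Grade < 2 -> ``healthy``; grade >= 3 -> ``damaged``; grade 2 raises
    :class:`GradeOutOfScopeError` (the study contrasts ICRS < 2 controls
    with ICRS >= 3 defects and has no place for intermediate damage).
    """
    if not 0 <= icrs_grade <= 4:
        raise GradeOutOfScopeError(f"ICRS grade must be 0-4, got {icrs_grade}")
    if icrs_grade == 2:
        raise GradeOutOfScopeError(
            "ICRS grade 2 is outside the two-class study design "
            "(healthy: grade < 2, damaged: grade >= 3)"
        )
    return "healthy" if icrs_grade < 2 else "damaged"


@dataclass(frozen=True)
class RegionAnnotation:
    """One surgeon-marked region: identity plus its ICRS grade."""

    patient_id: str
    region_id: int
    icrs_grade: int

    def __post_init__(self) -> None:
        if self.region_id <= 0:
            raise ValueError("region_id must be a positive integer")
        classify_grade(self.icrs_grade)

    @property
    def tissue_class(self) -> str:
        return classify_grade(self.icrs_grade)


def region_means(
    index: IndexImage, labels: np.ndarray, statistic: str = "mean"
) -> dict[int, tuple[float, int, int]]:
    """Per-region aggregate of an index image.

    Returns ``{region_id: (value, n_pixels, n_flagged)}`` for every non-zero
    label. Pixels flagged as degenerate in the index image (e.g. TWI with a
    vanishing denominator) are excluded from the aggregate and counted in
    ``n_flagged``; ``n_pixels`` counts the pixels that entered it.
    """
    labels = np.asarray(labels)
    if labels.shape != index.values.shape:
        raise ValueError("label map shape must match the index image")
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    valid = labels > 0
    if index.flags is not None:
        valid &= ~index.flags
    out: dict[int, tuple[float, int, int]] = {}
    for rid in np.unique(labels[labels > 0]):
        sel = valid & (labels == rid)
        n = int(sel.sum())
        n_flagged = int((labels == rid).sum()) - n
        if n == 0:
            out[int(rid)] = (float("nan"), 0, n_flagged)
            continue
        vals = index.values[sel]
        value = float(np.mean(vals) if statistic == "mean" else np.median(vals))
        out[int(rid)] = (value, n, n_flagged)
    return out


def extract_index_images(
    cube: AbsorbanceCube, twi_params: TWIParams = TWIParams()
) -> dict[str, IndexImage]:
    """The three parameter images of one absorbance cube."""
    return {
        "a540": band_value(cube, 540.0),
        "a960": band_value(cube, 960.0),
        "twi": twi(cube, twi_params),
    }


def build_region_table(
    acquisitions: Mapping[str, tuple[AbsorbanceCube, np.ndarray]],
    annotations: Iterable[RegionAnnotation],
    twi_params: TWIParams = TWIParams(),
    statistic: str = "mean",
) -> pd.DataFrame:
    """One row per annotated region with all three index means.

    ``acquisitions`` maps patient_id -> (absorbance cube, label map). Every
    annotated region must exist in its patient's label map
    (:class:`ConsistencyError` otherwise); grade-2 annotations are rejected
    at annotation construction. Rows are sorted by (patient_id, region_id);
    re-running on identical inputs yields an identical table.
    """
    annotations = list(annotations)
    per_patient: dict[str, dict[str, dict[int, tuple[float, int, int]]]] = {}
    for patient_id, (cube, labels) in acquisitions.items():
        images = extract_index_images(cube, twi_params)
        per_patient[patient_id] = {
            name: region_means(img, labels, statistic)
            for name, img in images.items()
        }
    rows = []
    for ann in annotations:
        if ann.patient_id not in per_patient:
            raise ConsistencyError(
                f"annotation for unknown patient {ann.patient_id!r}"
            )
        stats_by_index = per_patient[ann.patient_id]
        if ann.region_id not in stats_by_index["a540"]:
            raise ConsistencyError(
                f"region {ann.region_id} of patient {ann.patient_id} "
                "annotated but absent from the label map"
            )
        a540_v, n_px, _ = stats_by_index["a540"][ann.region_id]
        rows.append(
            {
                "patient_id": ann.patient_id,
                "region_id": ann.region_id,
                "tissue_class": ann.tissue_class,
                "icrs_grade": ann.icrs_grade,
                "n_pixels": n_px,
                "mean_a540": a540_v,
                "mean_a960": stats_by_index["a960"][ann.region_id][0],
                "mean_twi": stats_by_index["twi"][ann.region_id][0],
            }
        )
    table = pd.DataFrame(rows, columns=REGION_TABLE_COLUMNS)
    return table.sort_values(["patient_id", "region_id"]).reset_index(drop=True)


def paired_view(
    table: pd.DataFrame, index_name: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-patient paired vectors (healthy, damaged) for one index.

    Patients with several regions of a class contribute the average of those
    region means (one value per patient per class); patients missing either
    class are dropped from the pairing (they stay in the table). Raises
    :class:`InsufficientDataError` with fewer than 2 complete pairs.
    """
    col = INDEX_COLUMNS.get(index_name, index_name)
    if col not in table.columns:
        raise KeyError(f"no index column {index_name!r} in table")
    wide = (
        table.groupby(["patient_id", "tissue_class"])[col]
        .mean()
        .unstack("tissue_class")
    )
    for cls in ("healthy", "damaged"):
        if cls not in wide.columns:
            wide[cls] = np.nan
    complete = wide.dropna(subset=["healthy", "damaged"]).sort_index()
    if len(complete) < 2:
        raise InsufficientDataError(
            f"paired analysis needs >= 2 complete pairs, got {len(complete)}"
        )
    return (
        complete["healthy"].to_numpy(),
        complete["damaged"].to_numpy(),
        list(complete.index),
    )
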