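"""End-to-end pipeline: phantom cohort -> region table -> statistical report.

Also hosts the replicate driver used for calibration experiments: it runs
generate -> analyze over many seeds and aggregates operating-point rates,
AUCs and class-index means across replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import TWIParams, calibrate_reflectance, to_absorbance
from .io import config_digest
from .phantom import GeneratorConfig, PhantomScene, generate_cohort, sample_region_table
from .roi import build_region_table, paired_view
from .stats import (
    NEGATIVE_CLASS,
    POSITIVE_CLASS,
    operating_point,
    roc_curve,
    screen_parameters,
)

#: published decision threshold on the A540 patient-level ROI mean
DEFAULT_A540_THRESHOLD = 0.74


def scenes_to_table(
    scenes: list[PhantomScene],
    twi_params: TWIParams = TWIParams(),
    statistic: str = "mean",
) -> pd.DataFrame:
    """Calibrate every scene, extract indices and aggregate over regions."""
    acquisitions = {}
    annotations = []
    for scene in scenes:
        cube = to_absorbance(calibrate_reflectance(scene.raw, scene.references))
        acquisitions[scene.patient_id] = (cube, scene.labels)
        annotations.extend(scene.annotations)
    return build_region_table(acquisitions, annotations, twi_params, statistic)


def _patient_scores(table: pd.DataFrame, index_name: str):
    healthy, damaged, _ = paired_view(table, index_name)
    scores = np.concatenate([healthy, damaged])
    labels = np.array(
        [NEGATIVE_CLASS] * healthy.size + [POSITIVE_CLASS] * damaged.size
    )
    return scores, labels


def analyze_table(
    table: pd.DataFrame,
    threshold: float = DEFAULT_A540_THRESHOLD,
    alpha: float = 0.05,
) -> dict:
    """Full statistical report of one cohort table.

    Screens all three indices with the normality-routed paired test,
    computes ROC tables for significant indices, and always evaluates the
    fixed A540 operating point at ``threshold``.
    """
    report = screen_parameters(table, alpha=alpha)
    scores, labels = _patient_scores(table, "a540")
    report["a540_operating_point"] = operating_point(scores, labels, threshold)
    return report


def run_replicates(
    config: GeneratorConfig,
    n_replicates: int,
    base_seed: int = 0,
    roi_only: bool = True,
    threshold: float = DEFAULT_A540_THRESHOLD,
) -> tuple[pd.DataFrame, dict]:
    """Generate and analyze ``n_replicates`` cohorts with seeds
    ``base_seed + k``.

    Returns the per-replicate table (one row per cohort: class-index means,
    A540/TWI AUCs, operating-point sensitivity/specificity, paired-test
    p-values) and an aggregate dict with across-replicate mean and SD of
    every numeric column. ``roi_only=True`` draws region tables directly
    from the index targets; ``False`` realizes and re-analyzes full cubes.
    Deterministic given (config, base_seed).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []
    for k in range(n_replicates):
        cfg = GeneratorConfig(
            **{**_config_kwargs(config), "seed": base_seed + k}
        )
        if roi_only:
            table = sample_region_table(cfg)
        else:
            scenes, _ = generate_cohort(cfg)
            table = scenes_to_table(scenes, cfg.twi_params)
        row: dict = {"seed": cfg.seed}
        for index_name in ("a540", "a960", "twi"):
            healthy, damaged, _ = paired_view(table, index_name)
            row[f"mean_{index_name}_healthy"] = float(healthy.mean())
            row[f"mean_{index_name}_damaged"] = float(damaged.mean())
        report = screen_parameters(table)
        for index_name in ("a540", "a960", "twi"):
            row[f"p_{index_name}"] = report[index_name]["paired"].p_value
            row[f"test_{index_name}"] = report[index_name]["paired"].test_used
        for index_name in ("a540", "twi"):
            scores, labels = _patient_scores(table, index_name)
            row[f"auc_{index_name}"] = roc_curve(scores, labels).auc
        scores, labels = _patient_scores(table, "a540")
        op = operating_point(scores, labels, threshold)
        row["sensitivity"] = op.sensitivity
        row["specificity"] = op.specificity
        rows.append(row)
    per_replicate = pd.DataFrame(rows)
    numeric = per_replicate.select_dtypes(include=[np.number]).drop(columns=["seed"])
    aggregate = {
        "n_replicates": n_replicates,
        "base_seed": base_seed,
        "threshold": threshold,
        "config_digest": config_digest(config),
        "mean": {c: float(numeric[c].mean()) for c in numeric.columns},
        "sd": {c: float(numeric[c].std(ddof=1)) for c in numeric.columns},
    }
    return per_replicate, aggregate


def _config_kwargs(config: GeneratorConfig) -> dict:
    return {
        f.name: getattr(config, f.name)
        for f in config.__dataclass_fields__.values()
    }
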