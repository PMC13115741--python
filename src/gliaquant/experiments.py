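"""End-to-end synthetic experiments tying the modules together.

These functions are the scripted equivalents of the study's analyses, run on
synthetic cohorts:

* :func:`strategy_experiment` — train rule-compliant and rule-violating
  classifiers from programmatic scribbles and score their masks against
  ground truth (Dice/IoU) on a held-out test set of 25 cells from 4
  pseudo-animals (17 scar-resident, 8 non-scar, mirroring the validation
  dataset scale);
* :func:`scar_recovery_experiment` — the full single-cell pipeline (ROI,
  segmentation, size filter, minimum composite, morphometry) on a scar vs
  non-scar cohort, plus paired bootstrap effects per parameter and a
  length-weighted estimate of how much of the ground-truth process tree the
  masks capture;
* :func:`process_experiment` — process profiling of the ground-truth traces
  (whole/distal/proximal intensity, ratio, length, count) with paired
  effects;
* :func:`null_replicates` — repeated null cohorts measured on ground-truth
  masks, reporting Cohen's dz per parameter per replicate.

Problem sizes default to desk scale: 128 px canvases (38 x 38 um at
0.3 um/px), 25-cell strategy validation sets and ~100-cell cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cell_pipeline import (
    DEFAULT_MIN_AREA_PX,
    extract_square_mask,
    extract_square_roi,
    filter_objects_by_size,
    measure_cell,
)
from .evaluation_stats import (
    PairedEffect,
    compare_conditions,
    strategy_comparison,
)
from .pixel_classifier import (
    FeatureConfig,
    PixelClassifierModel,
    predict_mask,
    train_classifier,
)
from .process_analysis import (
    ProcessTrace,
    mask_coverage_counts,
    profile_process,
    summarize_processes,
)
from .synthetic_data import (
    Cohort,
    CohortConfig,
    SyntheticCell,
    generate_cohort,
    generate_scribbles,
)

MORPHOMETRY_PARAMS = (
    "mean_intensity",
    "area_um2",
    "perimeter_um",
    "area_to_perimeter_um",
    "circularity",
)

RULE_COMPLIANT_GROUP = "rule_compliant"
RULE_VIOLATING_GROUP = "rule_violating"


def _find_cell(cohort: Cohort, animal: int, condition: str, index: int) -> SyntheticCell:
    cid = f"a{animal}_{condition}_{index:02d}"
    for cell in cohort.cells:
        if cell.cell_id == cid:
            return cell
    raise KeyError(cid)


def train_strategy_classifier(
    cell: SyntheticCell,
    strategy: str,
    seed: int = 0,
    n_trees: int = 100,
    feature_config: FeatureConfig = FeatureConfig(),
) -> PixelClassifierModel:
    """Train one classifier from programmatic scribbles on one cell."""
    annotations = generate_scribbles(cell, strategy, seed=seed)
    return train_classifier(
        [(cell.image, annotations)],
        feature_config=feature_config,
        n_trees=n_trees,
        seed=seed,
        strategy_tag=strategy,
        image_ids=[cell.cell_id],
    )


@dataclass(frozen=True)
class StrategyExperimentResult:
    per_strategy_animal: pd.DataFrame
    group_mean_dice: dict
    group_mean_iou: dict
    n_test_cells: int


def strategy_experiment(
    seed: int = 0,
    n_trees: int = 100,
    min_area_px: float = DEFAULT_MIN_AREA_PX,
) -> StrategyExperimentResult:
    """Rule-compliant vs rule-violating annotation strategies, one seed.

    Six classifiers are trained on held-out cells of a 4-animal cohort:
    three rule-compliant (on different non-scar cells) and three
    rule-violating (core-only foreground, far background, scar-trained).
    Each segments the same 25-cell test set; Dice/IoU against ground-truth
    masks are averaged per animal and per strategy group.
    """
    cfg = CohortConfig(seed=int(seed) * 1000 + 17, cells_per_condition=7)
    cohort = generate_cohort(cfg)

    trainers = {
        "rc_1": ("rule_compliant", _find_cell(cohort, 0, "non_scar", 5)),
        "rc_2": ("rule_compliant", _find_cell(cohort, 1, "non_scar", 5)),
        "rc_3": ("rule_compliant", _find_cell(cohort, 2, "non_scar", 5)),
        "rv_core_only": ("rv_core_only", _find_cell(cohort, 3, "non_scar", 5)),
        "rv_far_background": ("rv_far_background", _find_cell(cohort, 0, "non_scar", 6)),
        "rv_scar_trained": ("rv_scar_trained", _find_cell(cohort, 1, "scar", 6)),
    }
    groups = {
        "rc_1": RULE_COMPLIANT_GROUP,
        "rc_2": RULE_COMPLIANT_GROUP,
        "rc_3": RULE_COMPLIANT_GROUP,
        "rv_core_only": RULE_VIOLATING_GROUP,
        "rv_far_background": RULE_VIOLATING_GROUP,
        "rv_scar_trained": RULE_VIOLATING_GROUP,
    }
    models = {
        name: train_strategy_classifier(cell, strategy, seed=seed, n_trees=n_trees)
        for name, (strategy, cell) in trainers.items()
    }

    # 25 test cells: 17 scar (5+4+4+4), 8 non-scar (2 per animal)
    test_cells = []
    for a in range(4):
        for i in range(5 if a == 0 else 4):
            test_cells.append(_find_cell(cohort, a, "scar", i))
        for i in range(2):
            test_cells.append(_find_cell(cohort, a, "non_scar", i))

    expert_masks = {}
    cell_animals = {}
    crops = {}
    for cell in test_cells:
        crops[cell.cell_id] = extract_square_roi(cell.image, cell.roi)
        expert_masks[cell.cell_id] = extract_square_mask(cell.mask, cell.roi)
        cell_animals[cell.cell_id] = cell.animal_id

    strategy_masks = {}
    for name, model in models.items():
        preds = {}
        for cid, crop in crops.items():
            raw = predict_mask(model, crop)
            preds[cid] = filter_objects_by_size(raw, min_area_px)
        strategy_masks[name] = preds

    table = strategy_comparison(expert_masks, strategy_masks, cell_animals, groups)
    group_dice = table.groupby("group")["mean_dice"].mean().to_dict()
    group_iou = table.groupby("group")["mean_iou"].mean().to_dict()
    return StrategyExperimentResult(
        per_strategy_animal=table,
        group_mean_dice=group_dice,
        group_mean_iou=group_iou,
        n_test_cells=len(test_cells),
    )


@dataclass(frozen=True)
class ScarRecoveryResult:
    records: pd.DataFrame
    effects: list[PairedEffect]
    coverage_fraction: float
    n_failed_rois: int


def scar_recovery_experiment(
    seed: int = 0,
    config: CohortConfig | None = None,
    n_boot: int = 10_000,
    n_trees: int = 100,
) -> ScarRecoveryResult:
    """Full pipeline on a scar vs non-scar cohort, with paired effects.

    A rule-compliant classifier is trained on one held-out non-scar cell;
    every other cell is cropped, segmented, size-filtered and measured. The
    coverage fraction is the pooled fraction of ground-truth trace points
    falling on the predicted (filtered) masks.
    """
    cfg = config if config is not None else CohortConfig(seed=int(seed) * 1000 + 29)
    cohort = generate_cohort(cfg)
    train_cell = _find_cell(cohort, 0, "non_scar", cfg.cells_per_condition - 1)
    model = train_strategy_classifier(
        train_cell, "rule_compliant", seed=seed, n_trees=n_trees
    )

    rows = []
    n_failed = 0
    hits = 0
    total = 0
    for cell in cohort.cells:
        if cell.cell_id == train_cell.cell_id:
            continue
        crop = extract_square_roi(cell.image, cell.roi)
        mask = filter_objects_by_size(predict_mask(model, crop), DEFAULT_MIN_AREA_PX)
        if not mask.pixels.any():
            n_failed += 1
            continue
        record = measure_cell(
            crop,
            mask,
            cell_id=cell.cell_id,
            animal_id=cell.animal_id,
            condition=cell.condition,
            classifier_id=model.metadata["scribble_fingerprint"][:8],
        )
        rows.append(record.__dict__)
        shifted = [
            ProcessTrace(
                t.cell_id,
                t.process_id,
                t.vertices - [cell.roi.x0, cell.roi.y0],
            )
            for t in cell.traces
        ]
        cell_hits, cell_total = mask_coverage_counts(shifted, mask)
        hits += cell_hits
        total += cell_total
    records = pd.DataFrame(rows)
    effects = compare_conditions(
        records, MORPHOMETRY_PARAMS, n_boot=n_boot, seed=seed
    )
    return ScarRecoveryResult(
        records=records,
        effects=effects,
        coverage_fraction=hits / total if total else float("nan"),
        n_failed_rois=n_failed,
    )


PROCESS_PARAMS = ("distal_to_proximal_ratio", "process_length_um", "n_processes")


@dataclass(frozen=True)
class ProcessExperimentResult:
    cell_table: pd.DataFrame
    effects: list[PairedEffect]


def process_experiment(
    seed: int = 0,
    config: CohortConfig | None = None,
    n_boot: int = 10_000,
) -> ProcessExperimentResult:
    """Process-level profiling of ground-truth traces, with paired effects.

    Profiles are taken on the raw (noisy) images; per cell the compartment
    ratio is averaged over analyzable (non-flagged) traces.
    """
    cfg = config if config is not None else CohortConfig(seed=int(seed) * 1000 + 43)
    cohort = generate_cohort(cfg)
    rows = []
    for cell in cohort.cells:
        profiles = [profile_process(cell.image, t) for t in cell.traces]
        summary = summarize_processes(profiles)[0]
        rows.append(
            {
                "cell_id": cell.cell_id,
                "animal_id": cell.animal_id,
                "condition": cell.condition,
                "distal_to_proximal_ratio": summary.mean_distal_to_proximal_ratio,
                "process_length_um": summary.mean_length_um,
                "n_processes": summary.n_processes,
            }
        )
    table = pd.DataFrame(rows).dropna(subset=["distal_to_proximal_ratio"])
    effects = compare_conditions(table, PROCESS_PARAMS, n_boot=n_boot, seed=seed)
    return ProcessExperimentResult(cell_table=table, effects=effects)


def null_replicates(
    seed: int = 0,
    n_replicates: int = 20,
    cells_per_condition: int = 10,
    n_boot: int = 1_000,
) -> pd.DataFrame:
    """Cohen's dz per morphometry parameter on repeated null cohorts.

    Cells are measured on their ground-truth masks, isolating the
    generator-plus-statistics null behavior from segmentation noise.
    Returns one row per (replicate, parameter) with the dz point estimate.
    """
    rows = []
    for r in range(n_replicates):
        cfg = CohortConfig.null(
            seed=int(seed) * 10_000 + r, cells_per_condition=cells_per_condition
        )
        cohort = generate_cohort(cfg)
        recs = []
        for cell in cohort.cells:
            crop = extract_square_roi(cell.image, cell.roi)
            gt = extract_square_mask(cell.mask, cell.roi)
            rec = measure_cell(
                crop,
                gt,
                cell_id=cell.cell_id,
                animal_id=cell.animal_id,
                condition=cell.condition,
                classifier_id="ground_truth",
            )
            recs.append(rec.__dict__)
        effects = compare_conditions(
            pd.DataFrame(recs), MORPHOMETRY_PARAMS, n_boot=n_boot, seed=seed + r
        )
        for e in effects:
            rows.append(
                {
                    "replicate": r,
                    "parameter": e.parameter,
                    "dz": e.dz,
                    "mean_diff": e.mean_diff,
                }
            )
    return pd.DataFrame(rows)
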