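"""End-to-end orchestration: masks + depth + camera in, PlantMeasure table out.

Per scene: leaves are assigned to plants by the >80 % overlap rule; for each
plant the stem attachment point is located from the leaf-plane intersections,
leaf lengths and allometric areas follow, and a head measure is added when a
head instance overlaps the plant. A plant whose stem cannot be located is
reported as an error record, never dropped silently — batch runs over a field
must complete.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Sequence

from .errors import CabbageMorphError
from .head_volume import DEFAULT_APEX_PERCENTILE, measure_head
from .io_formats import (
    CameraModel,
    DepthRaster,
    InstanceMask,
    backproject,
    write_measures,
)
from .leaf_morphometry import (
    DEFAULT_ASSIGN_THRESHOLD,
    DEFAULT_SHAPE_FACTOR,
    PlantMeasure,
    assign_leaves,
    measure_plant_leaves,
)
from .robust_plane import MsacConfig
from .seg_eval import accuracy_stats, column_stats
from .stem_locator import StemConfig, locate_stem
from . import reference_tables

logger = logging.getLogger("cabbagemorph")


@dataclass
class RunConfig:
    """All tunables of a measurement run in one place."""

    msac: MsacConfig = dc_field(default_factory=MsacConfig)
    stem: StemConfig = dc_field(default_factory=StemConfig)
    shape_factor: float = DEFAULT_SHAPE_FACTOR
    assign_threshold: float = DEFAULT_ASSIGN_THRESHOLD
    apex_percentile: float = DEFAULT_APEX_PERCENTILE
    eq_mode: Literal["pinhole", "literal"] = "pinhole"
    min_leaf_pixels: int = 30


@dataclass
class PlantError:
    """Failure record for one plant; keeps batch results complete."""

    plant_id: int
    error: str


def measure_scene(
    leaf_masks: Sequence[InstanceMask],
    plant_masks: Sequence[InstanceMask],
    head_masks: Sequence[InstanceMask],
    depth: DepthRaster,
    camera: CameraModel,
    config: RunConfig | None = None,
) -> tuple[list[PlantMeasure], list[PlantError], list[int]]:
    """Measure every plant in a co-registered scene.

    Returns (measures, per-plant error records, unassigned leaf ids). Every
    input leaf instance appears exactly once across the three outputs.
    """
    config = config or RunConfig()
    assignment = assign_leaves(leaf_masks, plant_masks, config.assign_threshold)
    unassigned = [lid for lid, pid in assignment.items() if pid is None]

    head_owner = assign_leaves(head_masks, plant_masks, 0.5)

    measures: list[PlantMeasure] = []
    errors: list[PlantError] = []
    for plant in plant_masks:
        pid = plant.instance_id
        my_leaves = [m for m in leaf_masks if assignment[m.instance_id] == pid]
        clouds = []
        for m in my_leaves:
            try:
                cloud = backproject(m, depth, camera)
            except CabbageMorphError:
                continue
            if len(cloud) < config.min_leaf_pixels:
                continue
            cloud.plant_id = pid
            clouds.append(cloud)
        try:
            attachment = locate_stem(
                clouds, plant, depth, camera, config.msac, config.stem
            )
            # lengths use the MSAC-cleaned clouds so depth outliers cannot
            # masquerade as leaf endpoints
            from .robust_plane import msac_filter

            clean = [msac_filter(c, config.msac) for c in clouds]
            measure = measure_plant_leaves(
                clean, attachment, plant_id=pid, shape_factor=config.shape_factor
            )
        except CabbageMorphError as exc:
            errors.append(PlantError(plant_id=pid, error=str(exc)))
            logger.warning("plant %d failed: %s", pid, exc)
            continue
        logger.info(
            "plant %d: support=%d dispersion=%.1f mm, %d leaves",
            pid,
            attachment.support,
            attachment.dispersion,
            len(measure.leaves),
        )
        my_head = [h for h in head_masks if head_owner.get(h.instance_id) == pid]
        if my_head:
            try:
                measure.head = measure_head(
                    my_head[0],
                    depth,
                    camera,
                    apex_percentile=config.apex_percentile,
                    eq_mode=config.eq_mode,
                )
            except CabbageMorphError as exc:
                measure.warnings.append(f"head measurement failed: {exc}")
        measures.append(measure)
    return measures, errors, unassigned


def measures_to_rows(measures: Sequence[PlantMeasure]) -> list[dict]:
    """Flatten PlantMeasure records to one row per plant plus one per leaf."""
    rows: list[dict] = []
    for pm in measures:
        plant_row = {
            "plant_id": pm.plant_id,
            "leaf_id": "",
            "length_mm": round(pm.mean_leaf_length, 3),
            "area_m2": round(pm.total_leaf_area, 6),
        }
        if pm.head is not None:
            plant_row["head_radius_mm"] = round(pm.head.radius_mm, 3)
            plant_row["head_volume_m3"] = round(pm.head.volume, 6)
        rows.append(plant_row)
        for leaf in pm.leaves:
            rows.append(
                {
                    "plant_id": pm.plant_id,
                    "leaf_id": leaf.leaf_id,
                    "length_mm": round(leaf.length, 3),
                    "area_m2": round(leaf.area, 6),
                }
            )
    return rows


def write_results(
    measures: Sequence[PlantMeasure],
    errors: Sequence[PlantError],
    out_dir: str | Path,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_measures(measures_to_rows(measures), out / "measures.csv")
    report = {
        "plants": [
            {
                "plant_id": pm.plant_id,
                "attachment_mm": list(pm.attachment.position),
                "support": pm.attachment.support,
                "dispersion_mm": pm.attachment.dispersion,
                "n_leaves": len(pm.leaves),
                "mean_leaf_length_mm": pm.mean_leaf_length,
                "total_leaf_area_m2": pm.total_leaf_area,
                "head_volume_m3": None if pm.head is None else pm.head.volume,
                "warnings": pm.warnings,
            }
            for pm in measures
        ],
        "errors": [{"plant_id": e.plant_id, "error": e.error} for e in errors],
    }
    with open(out / "measures.json", "w") as fh:
        json.dump(report, fh, indent=2)


# ---------------------------------------------------------------------------
# Reference-table reproduction
# ---------------------------------------------------------------------------

def reproduce_tables() -> dict[str, dict[str, float]]:
    """Recompute summary statistics of the bundled per-plant reference tables.

    For every table and column: mean, population SD in percent of the mean;
    plus mean accuracies following the tables' own reference convention —
    the calculated (ground-truth-mask) values are judged against the hand
    measurements, while the detected (network-mask) values are judged against
    the calculated ones, which are the method's ceiling. Derived per-leaf
    areas (mean LA / mean visible-leaf count) are included for the leaf-area
    tables.
    """
    out: dict[str, dict[str, float]] = {}
    for name, table in reference_tables.TABLES.items():
        stats: dict[str, float] = {}
        for col in table.columns:
            mean, sd, sd_pct = column_stats(table[col])
            stats[f"{col}_mean"] = mean
            stats[f"{col}_sd"] = sd
            stats[f"{col}_sd_percent"] = sd_pct
        if {"measured", "calculated"} <= set(table.columns):
            stats["calculated_mean_accuracy"] = accuracy_stats(
                table["measured"], table["calculated"]
            )
        if {"calculated", "detected"} <= set(table.columns):
            stats["detected_mean_accuracy"] = accuracy_stats(
                table["calculated"], table["detected"]
            )
        if "leaves_visible" in table.columns:
            stats["area_per_leaf_measured"] = (
                stats["measured_mean"] / stats["leaves_visible_mean"]
            )
        out[name] = stats
    return out
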