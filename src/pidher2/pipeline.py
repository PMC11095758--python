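"""Orchestration: simulate -> qc -> score -> classify -> concord as one run.

Every run writes its intermediate artifacts (scores.csv, classified.csv,
report.json), the resolved configuration, and a manifest with input digests
and per-stage row counts, so identical config + inputs reproduce identical
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .classify import (
    CutPoints,
    assign_pid_scores,
    consensus_dab,
    derive_cut_points,
    flag_ultra_low,
    negative_control_mean,
)
from .concordance import full_report
from .io import CoreRecord, read_core_image, read_cohort_table, read_mask, write_results
from .qc import apply_exclusions
from .scoring import EmptyMaskError, score_core
from .simulate import SimParams, simulate_cohort, truth_to_records

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending core."""

    def __init__(self, stage: str, message: str, core_id: str | None = None):
        self.stage = stage
        self.core_id = core_id
        where = f"stage {stage}" + (f", core {core_id}" if core_id else "")
        super().__init__(f"{where}: {message}")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    images_dir: str | None = None
    masks_dir: str | None = None
    cohort: str | None = None
    out_dir: str = "run_out"
    pixel_size_um: float = 0.46
    tile_size_um: float = 12.0
    top_fraction: float = 0.10
    inclusion_fraction: float = 0.5
    cut_point_mode: str = "derive"  # or "fixed"
    fixed_cuts: tuple[float, float, float] | None = None
    consensus_policy: str = "higher"
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("pixel_size_um", "tile_size_um", "top_fraction", "inclusion_fraction", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.cut_point_mode not in ("derive", "fixed"):
            raise ValueError(f"cut_point_mode must be 'derive' or 'fixed', got {self.cut_point_mode!r}")
        if self.cut_point_mode == "fixed":
            if self.fixed_cuts is None:
                raise ValueError("cut_point_mode 'fixed' requires fixed_cuts")
            CutPoints(*self.fixed_cuts)  # validates monotonicity

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fixed_cuts" in raw and raw["fixed_cuts"] is not None:
            raw["fixed_cuts"] = tuple(float(v) for v in raw["fixed_cuts"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def score_records(
    records: list[CoreRecord],
    images: dict[str, "object"],
    masks: dict[str, "object"],
    config: RunConfig,
) -> list[CoreRecord]:
    """Attach pid_value/n_tiles to every record with an image + mask pair."""
    for rec in records:
        if rec.core_id not in images:
            raise StageError("score", "no image for core", rec.core_id)
        if rec.core_id not in masks:
            raise StageError("score", "no mask for core", rec.core_id)
        try:
            result = score_core(
                images[rec.core_id],
                masks[rec.core_id],
                pixel_size_um=config.pixel_size_um,
                tile_size_um=config.tile_size_um,
                fraction=config.top_fraction,
                inclusion_fraction=config.inclusion_fraction,
            )
        except EmptyMaskError as exc:
            raise StageError("score", str(exc), rec.core_id) from exc
        rec.pid_value = result.pid_value
        rec.n_tiles = result.n_tiles
    return records


def run_pipeline(
    config: RunConfig,
    sim_params: SimParams | None = None,
    class_counts: dict[str, int] | None = None,
    n_negative_controls: int = 8,
    exclusion_plan: dict[str, list[str]] | None = None,
) -> dict:
    """Run the full chain and return the manifest.

    With ``sim_params`` given, the cohort is simulated (class_counts
    required); otherwise images/masks/cohort are read from the paths in
    ``config``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": dataclasses.asdict(config), "stages": {}}

    # --- inputs ---------------------------------------------------------
    if sim_params is not None:
        if not class_counts:
            raise StageError("simulate", "class_counts required when simulating")
        pairs, truths = simulate_cohort(
            sim_params,
            class_counts,
            n_negative_controls=n_negative_controls,
            exclusion_plan=exclusion_plan,
            seed=config.seed,
        )
        images = {img.core_id: img for img, _ in pairs}
        masks = {msk.core_id: msk for _, msk in pairs}
        records = truth_to_records(truths)
        manifest["stages"]["simulate"] = {"n_cores": len(records)}
    else:
        if not (config.cohort and config.images_dir and config.masks_dir):
            raise StageError("input", "images_dir, masks_dir and cohort paths are required")
        records = read_cohort_table(config.cohort)
        manifest["inputs"] = {"cohort_sha256": _sha256(Path(config.cohort))}
        images, masks = {}, {}
        img_dir, msk_dir = Path(config.images_dir), Path(config.masks_dir)
        for rec in records:
            ipath = img_dir / f"{rec.core_id}.tif"
            if not ipath.exists():
                raise StageError("input", f"missing image {ipath}", rec.core_id)
            images[rec.core_id] = read_core_image(ipath, config.pixel_size_um, core_id=rec.core_id)
            mpath = msk_dir / f"{rec.core_id}.png"
            if not mpath.exists():
                mpath = msk_dir / f"{rec.core_id}.tif"
            if not mpath.exists():
                raise StageError("input", f"missing mask for core in {msk_dir}", rec.core_id)
            masks[rec.core_id] = read_mask(mpath, core_id=rec.core_id)

    # consensus DAB
    for rec in records:
        if rec.dab_consensus is None:
            rec.dab_consensus = consensus_dab(
                rec.dab_score_p1, rec.dab_score_p2, policy=config.consensus_policy, core_id=rec.core_id
            )

    # --- qc -------------------------------------------------------------
    analyzable, summary = apply_exclusions(records)
    manifest["stages"]["qc"] = {
        "input": len(records),
        "excluded": summary.excluded_total,
        "excluded_percent": summary.excluded_percent,
        "analyzable": summary.analyzable,
        "negative_controls": summary.n_negative_controls,
        "counts": summary.counts,
    }
    if not analyzable:
        raise StageError("score", "no analyzable cores remain after exclusion")

    # --- score (analyzable + negative controls) -------------------------
    controls = [r for r in records if r.is_negative_control and r.exclusion_reason == "none"]
    score_records(analyzable + controls, images, masks, config)
    manifest["stages"]["score"] = {"scored": len(analyzable), "negative_controls_scored": len(controls)}
    scores_df_records = analyzable + controls
    import pandas as pd

    pd.DataFrame(
        [{"core_id": r.core_id, "n_tiles": r.n_tiles, "pid_value": r.pid_value} for r in scores_df_records]
    ).to_csv(out / "scores.csv", index=False)

    # --- classify -------------------------------------------------------
    if config.cut_point_mode == "fixed":
        cuts = CutPoints(*config.fixed_cuts)
    else:
        cuts = derive_cut_points(analyzable)
    assign_pid_scores(analyzable, cuts)
    manifest["stages"]["classify"] = {"cut_points": [cuts.c1, cuts.c2, cuts.c3], "mode": config.cut_point_mode}
    if controls:
        ncs = negative_control_mean(controls)
        flag_ultra_low(analyzable, cuts, ncs)
        manifest["stages"]["classify"]["negative_control_mean"] = ncs.mean_value
        manifest["stages"]["classify"]["negative_control_n"] = ncs.n
    write_results(out / "classified.csv", analyzable)

    # --- concordance ----------------------------------------------------
    report = full_report(analyzable, alpha=config.alpha)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    manifest["stages"]["concord"] = {"n": report.n, "r_squared": report.r_squared}

    (out / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
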