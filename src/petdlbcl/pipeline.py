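"""End-to-end pipeline: simulate -> quantify -> score -> survival -> model.

Each stage persists its artefacts under the output directory and later
stages re-read them from disk, so a missing intermediate fails loudly with a
stage-named error.  All randomness flows from the config seed; a fixed seed
gives byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, simulate_cohort_df
from .config import PipelineConfig, config_hash
from .io import (
    read_cohort,
    read_mask,
    read_volume,
    write_cohort,
    write_mask,
    write_segmentation,
    write_volume,
)
from .model import summarise_model
from .phantom import demo_phantom_spec, generate_phantom
from .scoring import ReferenceRegions, assess_response
from .segmentation import segment_mtv, segment_mtv_pct
from .survival import cox_regression_table, tertile_groups

__all__ = ["PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


def _stage(stage: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
                raise PipelineStageError(stage, str(exc)) from exc

        return wrapper

    return deco


@_stage("simulate")
def _simulate(config: PipelineConfig, out: Path) -> dict:
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(2**31, size=3)
    for tag, interim in (("baseline", False), ("interim", True)):
        spec = demo_phantom_spec(
            seed=int(seeds[0 if tag == "baseline" else 1]),
            interim=interim,
            noise_sd=config.simulation.phantom_noise_sd,
            blur_fwhm=config.simulation.phantom_blur_fwhm,
        )
        vol, truth = generate_phantom(spec)
        write_volume(vol, out / f"{tag}.nii")
        for name, mask in truth.region_masks.items():
            write_mask(mask, vol.spacing, out / f"{tag}_{name}_mask.nii")
        write_mask(truth.lesion_mask > 0, vol.spacing, out / f"{tag}_truth_mask.nii")
        (out / f"{tag}_spec.json").write_text(spec.to_json() + "\n")
    cohort = simulate_cohort_df(CohortSpec(n=config.simulation.cohort_n, seed=int(seeds[2])))
    write_cohort(cohort, out / "cohort.csv")
    return {"cohort_n": int(len(cohort))}


@_stage("quantify")
def _quantify(config: PipelineConfig, out: Path) -> dict:
    lesions = {}
    for tag in ("baseline", "interim"):
        mask = read_mask(out / f"{tag}_bladder_mask.nii")  # physiological exclusion
        vol = read_volume(out / f"{tag}.nii", edit_mask=mask)
        if config.segmentation.mode == "pct41":
            seg = segment_mtv_pct(
                vol,
                fraction=config.segmentation.fraction,
                detect_threshold=config.segmentation.threshold,
                min_voxels=config.segmentation.min_voxels,
            )
        else:
            seg = segment_mtv(
                vol,
                threshold=config.segmentation.threshold,
                min_voxels=config.segmentation.min_voxels,
            )
        write_segmentation(seg, out / f"{tag}_seg.json", out / f"{tag}_labels.nii")
        lesions[tag] = seg.n_lesions
    return {"n_lesions": lesions}


@_stage("score")
def _score(config: PipelineConfig, out: Path) -> dict:
    vol = read_volume(out / "interim.nii")
    liver = read_mask(out / "interim_liver_mask.nii")
    medi = read_mask(out / "interim_mediastinum_mask.nii")
    base_vol = read_volume(out / "baseline.nii", edit_mask=read_mask(out / "baseline_bladder_mask.nii"))
    interim_vol = read_volume(out / "interim.nii", edit_mask=read_mask(out / "interim_bladder_mask.nii"))
    baseline_seg = segment_mtv(base_vol, threshold=config.segmentation.threshold)
    interim_seg = segment_mtv(interim_vol, threshold=config.segmentation.threshold)
    refs = ReferenceRegions.from_masks(vol, liver, medi, tumour_labels=interim_seg.label_map)
    assessment = assess_response(baseline_seg, interim_seg, refs)
    (out / "response.json").write_text(json.dumps(assessment.to_dict(), indent=2) + "\n")
    return {"deauville": assessment.deauville, "category": assessment.category.value}


@_stage("survival")
def _survival(config: PipelineConfig, out: Path) -> dict:
    df = read_cohort(out / "cohort.csv")
    work = df.dropna(subset=["mtv0", "ds", "time_years"]).copy()
    work["mtv0_tertile"] = tertile_groups(work["mtv0"].to_numpy(float))
    table = cox_regression_table(
        work,
        "time_years",
        "event",
        factors={"MTV-0 tertile": "mtv0_tertile", "DS": "ds"},
        multivariate=["MTV-0 tertile", "DS"],
    )
    table.to_csv(out / "cox_table.csv", index=False)
    return {"n": int(len(work))}


@_stage("model")
def _model(config: PipelineConfig, out: Path) -> dict:
    df = read_cohort(out / "cohort.csv")
    results = summarise_model(
        df,
        grouping=config.grouping,
        cutoffs=config.cutoffs.to_cutoffs(),
        landmark_years=config.survival.landmark_years,
    )
    (out / "model_summary.json").write_text(json.dumps(results.to_dict(), indent=2) + "\n")
    results.group_table.to_csv(out / "model_groups.csv")
    (out / "model_summary.txt").write_text(results.summary() + "\n")
    return {"n": results.n, "events": results.total_events}


def run_pipeline(config: PipelineConfig, outdir: str | Path):
    """Run all stages into ``outdir`` and return the fitted model results."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    log["stages"]["simulate"] = _simulate(config, out)
    log["stages"]["quantify"] = _quantify(config, out)
    log["stages"]["score"] = _score(config, out)
    log["stages"]["survival"] = _survival(config, out)
    log["stages"]["model"] = _model(config, out)
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")

    df = read_cohort(out / "cohort.csv")
    return summarise_model(
        df,
        grouping=config.grouping,
        cutoffs=config.cutoffs.to_cutoffs(),
        landmark_years=config.survival.landmark_years,
    )
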