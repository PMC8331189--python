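"""Orchestration: simulate -> detect -> normalize -> stats.

Per-image quantitation helpers compose the low-level operations in the
canonical order (fine filter, ratio image, region restriction, detection),
and :func:`run_pipeline` drives a whole simulated study from one
:class:`~mitoquant.io.PipelineConfig`, writing record tables, subject
summaries, a statistics report and a run manifest.  Everything downstream
of the seed is deterministic.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from mitoquant import detect, stats, tissue
from mitoquant.detect import PunctaSet, ThresholdConfig
from mitoquant.images import RegionMask, ReporterImage
from mitoquant.io import ArmSpec, PipelineConfig, RunManifest
from mitoquant.synthetic import CountDistribution, SceneSpec, render_mef_scene
from mitoquant import __version__

logger = logging.getLogger("mitoquant")

DATA_DICTIONARY = {
    "image_id": "unique image identifier",
    "subject_id": "subject (animal / culture) identifier",
    "genotype": "genotype tag (e.g. WT, G2019S, KO)",
    "treatment": "treatment tag (e.g. vehicle, inhibitor, DFP, EBSS, none)",
    "cell_type": "immunolabelled population the counts are restricted to",
    "n_mitolysosomes": "detected red-only (high-ratio, high-red) objects",
    "n_autophagosomes": "detected high-red objects with low red/green ratio",
    "n_autolysosomes": "detected high-red objects with high red/green ratio",
    "stained_area_um2": "area of the population mask in square micrometres",
    "n_cell_bodies": "soma-scale connected components in the population mask",
    "mitolysosomes_per_um2": "n_mitolysosomes / stained_area_um2",
    "mitolysosomes_per_cell": "n_mitolysosomes / n_cell_bodies",
    "autophagosomes_per_um2": "n_autophagosomes / stained_area_um2",
    "autolysosomes_per_um2": "n_autolysosomes / stained_area_um2",
    "pct_autophagosomes_colocalized": "% autophagosomes overlapping the mito mask",
    "pct_autolysosomes_colocalized": "% autolysosomes overlapping the mito mask",
}


# ---------------------------------------------------------------------------
# per-image quantitation
# ---------------------------------------------------------------------------


def preprocess(image: ReporterImage, cfg: ThresholdConfig):
    """Fine-filter both reporter channels and build the ratio image."""
    red = detect.fine_filter(image.red, cfg.fine_filter_radius)
    green = detect.fine_filter(image.green, cfg.fine_filter_radius)
    ratio = detect.compute_ratio_image(red, green, cap=cfg.ratio_cap)
    return red, green, ratio


def quantify_mito_image(
    image: ReporterImage,
    cfg: ThresholdConfig,
    region: Optional[RegionMask] = None,
) -> PunctaSet:
    """Full mitolysosome detection on one image.

    When no region is given the whole field is eligible (cultured-cell
    mode); tissue mode passes a green-threshold or immunolabel mask.
    """
    red, green, ratio = preprocess(image, cfg)
    if region is None:
        region = RegionMask(
            np.ones(image.shape, dtype=bool), image.pixel_size, "tissue",
            source="full_field",
        )
    return detect.detect_mitolysosomes(
        ratio, red, region, cfg, green=green, image_id=image.image_id
    )


def quantify_auto_image(
    image: ReporterImage,
    cfg: ThresholdConfig,
    region: Optional[RegionMask] = None,
    pixelwise: bool = False,
) -> PunctaSet:
    """Autophagosome/autolysosome detection and classification."""
    red, green, ratio = preprocess(image, cfg)
    if region is None:
        region = RegionMask(
            np.ones(image.shape, dtype=bool), image.pixel_size, "tissue",
            source="full_field",
        )
    return detect.detect_and_classify_auto_puncta(
        red, ratio, region, cfg, green=green, image_id=image.image_id,
        pixelwise=pixelwise,
    )


# ---------------------------------------------------------------------------
# whole-study simulation + quantitation
# ---------------------------------------------------------------------------


def _scene_seed(base_seed: int, arm_idx: int, subject_idx: int, image_idx: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), arm_idx, subject_idx, image_idx])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def _arm_scene(base: SceneSpec, arm: ArmSpec, seed: int) -> SceneSpec:
    d = base.to_dict()
    d["seed"] = seed
    d["n_mitolysosomes_per_cell"] = {
        "mean": arm.mito_count_mean,
        "dispersion": base.n_mitolysosomes_per_cell.dispersion,
    }
    return SceneSpec.from_dict(d)


def simulate_and_quantify(config: PipelineConfig) -> pd.DataFrame:
    """Render every scene of the configured study and quantify it.

    Returns the per-image :class:`~mitoquant.tissue.QuantRecord` table.
    """
    records = []
    for arm_idx, arm in enumerate(config.arms):
        for subj_idx in range(arm.n_subjects):
            subject_id = f"{arm.genotype}-{arm.treatment}-s{subj_idx:02d}"
            for img_idx in range(arm.n_images_per_subject):
                seed = _scene_seed(config.seed, arm_idx, subj_idx, img_idx)
                spec = _arm_scene(config.scene, arm, seed)
                image, rois, truth = render_mef_scene(
                    spec,
                    meta={
                        "image_id": f"{subject_id}-i{img_idx:02d}",
                        "subject_id": subject_id,
                        "genotype": arm.genotype,
                        "treatment": arm.treatment,
                    },
                )
                puncta = quantify_mito_image(image, config.thresholds)
                per_cell = detect.count_per_cell(puncta, rois)
                in_cells = per_cell[per_cell["cell_id"] >= 0]["n_puncta"]
                n_cells = len(rois)
                field_mask = RegionMask(
                    np.ones(image.shape, dtype=bool), image.pixel_size, "tissue"
                )
                rec = tissue.QuantRecord(
                    image_id=image.image_id,
                    subject_id=subject_id,
                    genotype=arm.genotype,
                    treatment=arm.treatment,
                    cell_type="all",
                    n_mitolysosomes=len(puncta),
                    stained_area_um2=field_mask.area_um2,
                    n_cell_bodies=n_cells,
                    mitolysosomes_per_um2=tissue.normalize_per_area(
                        int(in_cells.sum()), field_mask
                    ),
                    mitolysosomes_per_cell=tissue.normalize_per_cell(
                        int(in_cells.sum()), n_cells
                    ),
                )
                records.append(rec)
                logger.debug("quantified %s: %d mitolysosomes",
                             image.image_id, len(puncta))
    return tissue.records_to_dataframe(records)


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict[str, Path]:
    """Execute the whole study and write its outputs.

    Writes ``records.csv`` (per image), ``subject_summaries.csv``,
    ``anova.csv`` / ``tukey.csv`` / ``stats_report.txt`` (when the design
    supports them), ``data_dictionary.csv`` and ``manifest.json``.
    Deterministic given the config seed; returns the paths written.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    stage = "simulate+detect"
    try:
        records = simulate_and_quantify(config)
        if records.empty:
            logger.warning("no images produced; writing empty outputs")

        stage = "normalize"
        records_path = out / "records.csv"
        records.to_csv(records_path, index=False)
        written["records"] = records_path

        dd = pd.DataFrame(
            [{"column": k, "description": v} for k, v in DATA_DICTIONARY.items()]
        )
        dd_path = out / "data_dictionary.csv"
        dd.to_csv(dd_path, index=False)
        written["data_dictionary"] = dd_path

        stage = "stats"
        report_lines = [f"mitoquant {__version__} statistics report", ""]
        if not records.empty:
            summaries = stats.summarize_by_subject(
                records, "mitolysosomes_per_cell"
            )
            summ_path = out / "subject_summaries.csv"
            summaries.to_csv(summ_path, index=False)
            written["subject_summaries"] = summ_path

            factors = ["genotype"]
            if summaries["treatment"].nunique() > 1:
                factors.append("treatment")
            enough_levels = all(summaries[f].nunique() >= 2 for f in factors)
            enough_subjects = (
                summaries.groupby(factors).size().min() >= 2
                if enough_levels else False
            )
            if enough_levels and enough_subjects:
                anova, tukey = stats.anova_tukey(
                    summaries, "mean_mitolysosomes_per_cell", factors
                )
                anova_path = out / "anova.csv"
                anova.table.to_csv(anova_path, index=False)
                written["anova"] = anova_path
                tukey_path = out / "tukey.csv"
                tukey.table.to_csv(tukey_path, index=False)
                written["tukey"] = tukey_path
                report_lines.append(f"ANOVA model: {anova.formula}")
                report_lines.extend(f"  warning: {w}" for w in anova.warnings)
                report_lines.append(anova.table.to_string(index=False))
                report_lines.append("")
                report_lines.append("Tukey HSD (all cell pairs):")
                report_lines.append(tukey.table.to_string(index=False))
            else:
                report_lines.append(
                    "design too small for ANOVA (need >= 2 levels and >= 2 "
                    "subjects per cell)"
                )
        else:
            report_lines.append("no records")
        report_lines.append("")
        report_lines.append("thresholds used: "
                            f"{config.thresholds.to_dict()}")
        report_path = out / "stats_report.txt"
        report_path.write_text("\n".join(report_lines) + "\n")
        written["stats_report"] = report_path

        stage = "manifest"
        manifest = RunManifest(
            config_hash=config.config_hash(),
            version=__version__,
            inputs=[],
        )
        manifest_path = out / "manifest.json"
        manifest.write(manifest_path)
        written["manifest"] = manifest_path
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return written
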