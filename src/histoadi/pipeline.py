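"""End-to-end orchestration: tile -> classify -> score -> survive -> enrich.

Each stage is a pure function of its declared inputs; the run report
echoes the config and seed, so a run is reproducible from its report
alone. Stages whose inputs are absent are skipped with a warning rather
than failing the run.
"""

from __future__ import annotations

import json
import math
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from histoadi import io
from histoadi.classification import (
    ClassifierModel,
    classify_tiles,
    train_reference_classifier,
)
from histoadi.config import PipelineConfig, config_as_dict
from histoadi.enrichment import compare_groups, read_gmt, ssgsea
from histoadi.labels import CLASS_LABELS
from histoadi.scoring import aggregate_patient, composition
from histoadi.survival import stratify_and_test
from histoadi.synthetic import default_texture, generate_tile
from histoadi.tiling import tile_slide


@dataclass
class RunReport:
    config: dict
    seed: int
    stage_counts: dict[str, int] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    wall_time_s: float = 0.0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, default=str)


def train_synthetic_reference_model(
    tiles_per_class: int = 60, seed: int = 0
) -> ClassifierModel:
    """Train the reference classifier on freshly generated synthetic tiles."""
    tiles, labels = [], []
    for lab in CLASS_LABELS:
        for i in range(tiles_per_class):
            sub_seed = (seed * 900_001 + CLASS_LABELS.index(lab) * 10_007 + i) & 0x7FFFFFFF
            tiles.append(generate_tile(default_texture(lab, seed=sub_seed)))
            labels.append(lab)
    return train_reference_classifier(tiles, labels, seed=seed)


def score_slides(
    slide_paths: list[Path], model: ClassifierModel, config: PipelineConfig
) -> tuple[pd.DataFrame, list, list]:
    """Tile, classify and score each slide; one patient per slide stem.

    Returns (score table, tiling reports, predictions). Slides sharing a
    patient id prefix "<patient>__<slide>" are pooled per patient.
    """
    reports, all_predictions = [], []
    per_patient: dict[str, list] = {}
    for path in slide_paths:
        slide, _ = io.read_slide(path)
        kept, report = tile_slide(
            slide,
            tile_px=config.tile_px,
            target_mpp=config.target_mpp,
            background_threshold=config.background_threshold,
        )
        reports.append(report)
        predictions = classify_tiles(kept, model)
        all_predictions.extend(predictions)
        comp = composition(predictions)
        comp.n_prefiltered_background = report.n_background
        patient_id = slide.slide_id.split("__")[0]
        per_patient.setdefault(patient_id, []).append(comp)

    scores = [aggregate_patient(pid, comps) for pid, comps in sorted(per_patient.items())]
    table = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in scores],
            "n_tiles": [s.n_tiles for s in scores],
            "adi": [s.adi for s in scores],
        }
    )
    return table, reports, all_predictions


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all configured stages and write results under out_dir."""
    t0 = _time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config_as_dict(config), seed=config.seed)

    def emit(path: Path) -> Path:
        report.outputs.append(str(path))
        return path

    # --- classification model
    scores_df: pd.DataFrame | None = None
    if config.slides_dir is not None:
        slide_paths = sorted(Path(config.slides_dir).glob("*.png"))
        if not slide_paths:
            raise FileNotFoundError(f"no .png slides under {config.slides_dir}")
        if config.model_path is not None:
            model = ClassifierModel.load(config.model_path)
        else:
            model = train_synthetic_reference_model(
                tiles_per_class=config.train_tiles_per_class, seed=config.seed
            )
            model.save(emit(out / "reference_model.joblib"))
        report.stage_counts["slides"] = len(slide_paths)

        scores_df, tiling_reports, predictions = score_slides(
            slide_paths, model, config
        )
        io.write_tiling_reports(tiling_reports, emit(out / "tiling_report.tsv"))
        io.write_predictions(predictions, emit(out / "predictions.tsv"))
        scores_df.to_csv(
            emit(out / "patient_scores.tsv"), sep="\t", index=False, float_format="%.6g"
        )
        report.stage_counts["tiles_classified"] = len(predictions)
        report.stage_counts["patients_scored"] = len(scores_df)

    # --- survival
    groups_by_patient: pd.Series | None = None
    if config.survival_table is not None:
        surv = io.read_survival_table(config.survival_table)
        if scores_df is not None:
            # image-derived scores supersede any adi column in the table
            merged = surv.drop(columns=["adi"], errors="ignore").merge(
                scores_df[["patient_id", "adi"]], on="patient_id"
            )
        elif "adi" in surv.columns:
            merged = surv
        else:
            merged = None
            report.warnings.append(
                "survival stage skipped: no ADI scores (no slides and no adi column)"
            )
        if merged is not None and len(merged) >= 4:
            merged = merged.dropna(subset=["adi", "time", "event"])
            result = stratify_and_test(
                merged["time"],
                merged["event"],
                merged["adi"],
                method=config.stratification,
                minprop=config.minprop,
            )
            summary = {
                "method": result.method,
                "threshold": result.threshold,
                "n_high": result.n_high,
                "n_low": result.n_low,
                "events_high": result.events_high,
                "events_low": result.events_low,
                "logrank_chi2": result.logrank.chi2,
                "logrank_p": result.logrank.p_value,
                "cox_beta": result.cox.beta,
                "hr": result.cox.hr,
                "hr_ci_low": result.cox.ci_low,
                "hr_ci_high": result.cox.ci_high,
                "reliable": result.reliable,
            }
            (emit(out / "survival_summary.json")).write_text(
                json.dumps(summary, indent=1) + "\n"
            )
            km_rows = []
            for grp, curve in (("high", result.km_high), ("low", result.km_low)):
                for t, s, r, d in zip(
                    curve.event_times, curve.survival, curve.at_risk, curve.n_events
                ):
                    km_rows.append(
                        {"group": grp, "time": t, "survival": s, "at_risk": r, "events": d}
                    )
            pd.DataFrame(km_rows).to_csv(
                emit(out / "km_curves.tsv"), sep="\t", index=False, float_format="%.6g"
            )
            groups_by_patient = pd.Series(
                np.where(merged["adi"] > result.threshold, "high", "low"),
                index=merged["patient_id"].astype(str).to_numpy(),
            )
            report.stage_counts["patients_survival"] = len(merged)
        elif merged is not None:
            report.warnings.append("survival stage skipped: fewer than 4 complete records")

    # --- enrichment
    if config.expression is not None and config.gene_sets is not None:
        expr = io.read_expression(config.expression)
        sets = read_gmt(config.gene_sets)
        scores = ssgsea(expr, sets, alpha=config.ssgsea_alpha)
        scores.to_csv(emit(out / "ssgsea_scores.tsv"), sep="\t", float_format="%.6g")
        report.stage_counts["gene_sets_scored"] = len(scores)
        if groups_by_patient is not None:
            groups = groups_by_patient.reindex(scores.columns)
            if groups.notna().all() and (groups == "high").sum() >= 2 and (
                groups == "low"
            ).sum() >= 2:
                cmp_table = compare_groups(scores, groups, test=config.group_test)
                cmp_table.to_csv(
                    emit(out / "group_comparison.tsv"), sep="\t", float_format="%.6g"
                )
            else:
                report.warnings.append(
                    "group comparison skipped: expression samples not matched to groups"
                )
        else:
            report.warnings.append("group comparison skipped: no survival grouping")
    elif config.expression is not None or config.gene_sets is not None:
        report.warnings.append(
            "enrichment skipped: needs both an expression matrix and a GMT file"
        )

    report.wall_time_s = round(_time.perf_counter() - t0, 3)
    (out / "run_report.json").write_text(report.to_json() + "\n")
    report.outputs.append(str(out / "run_report.json"))
    return report
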