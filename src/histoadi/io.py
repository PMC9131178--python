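"""File formats: slides as PNG + JSON sidecar, tables as TSV.

A slide on disk is ``<stem>.png`` (plain raster RGB) next to
``<stem>.json`` carrying the declared microns-per-pixel and, for
synthetic slides, the ground-truth label grid. Cohorts, patient scores,
tiling reports and enrichment results are tab-separated tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from histoadi.scoring import PatientScore
from histoadi.tiling import SlideImage, TilingReport
from histoadi.labels import CLASS_LABELS


def write_slide(
    slide: SlideImage,
    path: str | Path,
    label_grid: np.ndarray | None = None,
) -> tuple[Path, Path]:
    """Write a slide as PNG plus its JSON sidecar; returns both paths."""
    path = Path(path)
    if path.suffix.lower() != ".png":
        path = path.with_suffix(".png")
    iio.imwrite(path, slide.pixels)
    sidecar = {"slide_id": slide.slide_id, "mpp": slide.mpp}
    if label_grid is not None:
        sidecar["label_grid"] = np.asarray(label_grid).astype(str).tolist()
    sidecar_path = path.with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=1) + "\n")
    return path, sidecar_path


def read_slide(path: str | Path) -> tuple[SlideImage, np.ndarray | None]:
    """Read a PNG slide and its sidecar; returns (slide, label grid or None)."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"slide sidecar {sidecar_path} not found; a declared mpp is required"
        )
    sidecar = json.loads(sidecar_path.read_text())
    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    if pixels.shape[2] == 4:
        pixels = pixels[..., :3]
    slide = SlideImage(
        slide_id=str(sidecar.get("slide_id", path.stem)),
        pixels=pixels.astype(np.uint8),
        mpp=float(sidecar["mpp"]),
    )
    grid = sidecar.get("label_grid")
    labels = np.asarray(grid, dtype="<U4") if grid is not None else None
    return slide, labels


def write_tiling_reports(reports: list[TilingReport], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "slide_id": r.slide_id,
                "total": r.n_total,
                "removed": r.n_background,
                "kept": r.n_kept,
            }
            for r in reports
        ]
    ).to_csv(path, sep="\t", index=False)


def write_patient_scores(scores: list[PatientScore], path: str | Path) -> None:
    """Patient score table: patient_id, n_tiles, adi, nine proportion columns."""
    rows = []
    for s in scores:
        row = {"patient_id": s.patient_id, "n_tiles": s.n_tiles, "adi": s.adi}
        for lab, p in zip(CLASS_LABELS, s.proportions):
            row[f"prop_{lab}"] = p
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_patient_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_predictions(predictions, path: str | Path) -> None:
    """Prediction table: slide_id, row, col, label, nine probability columns."""
    rows = []
    for p in predictions:
        row = {"slide_id": p.slide_id, "row": p.row, "col": p.col, "label": p.label}
        for lab, prob in zip(CLASS_LABELS, p.probabilities):
            row[f"p_{lab}"] = prob
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_survival_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_survival_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table lacks columns: {sorted(missing)}")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV with gene ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError("expression matrix has duplicate gene ids")
    return df


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6g")
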