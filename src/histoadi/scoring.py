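"""Tissue-composition aggregation and the adipose (ADI) score.

The ADI score of a slide is the fraction of its classified tiles labeled
adipose: a slide with 1,000 classified tiles of which 200 carry the ADI
label scores 0.2. By default the denominator is *all* classified tiles,
including any the model labels BACK after the pre-filter (the pre-filter
removes most background before classification; tiles it removed are
never in the denominator). Multi-slide patients are pooled by summing
counts, which weights each slide by its tile count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from histoadi.labels import ADI_INDEX, CLASS_LABELS


@dataclass
class SlideComposition:
    """Per-slide tile counts over the nine classes."""

    slide_id: str
    counts: dict[str, int]
    n_prefiltered_background: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels in counts: {sorted(unknown)}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be >= 0")
        self.counts = {lab: int(self.counts.get(lab, 0)) for lab in CLASS_LABELS}

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())


@dataclass
class PatientScore:
    """Pooled tissue proportions and ADI score for one patient."""

    patient_id: str
    adi: float
    proportions: np.ndarray  # 9-vector in canonical class order
    n_tiles: int


def composition(predictions: Sequence) -> SlideComposition:
    """Count predicted labels for one slide's prediction stream.

    All predictions must share a slide_id; an empty stream yields an
    all-zero composition with slide_id "".
    """
    counts = {lab: 0 for lab in CLASS_LABELS}
    slide_ids = {p.slide_id for p in predictions}
    if len(slide_ids) > 1:
        raise ValueError(f"predictions mix slides: {sorted(slide_ids)}")
    for p in predictions:
        counts[p.label] += 1
    slide_id = slide_ids.pop() if slide_ids else ""
    return SlideComposition(slide_id=slide_id, counts=counts)


def adi_score(comp: SlideComposition, exclude_model_background: bool = False) -> float:
    """ADI fraction of a slide: ADI count over classified tiles.

    With ``exclude_model_background`` the denominator drops tiles the
    model itself labeled BACK. A slide with zero (eligible) classified
    tiles has no defined score and returns NaN -- never 0.
    """
    denom = comp.n_classified
    if exclude_model_background:
        denom -= comp.counts["BACK"]
    if denom <= 0:
        return math.nan
    return comp.counts["ADI"] / denom


def aggregate_patient(
    patient_id: str, compositions: Iterable[SlideComposition]
) -> PatientScore:
    """Pool class counts across a patient's slides, then take proportions."""
    comps = list(compositions)
    if not comps:
        raise ValueError("a patient needs at least one slide composition")
    pooled = np.zeros(len(CLASS_LABELS), dtype=float)
    for comp in comps:
        pooled += [comp.counts[lab] for lab in CLASS_LABELS]
    n_tiles = int(pooled.sum())
    if n_tiles == 0:
        return PatientScore(
            patient_id=patient_id,
            adi=math.nan,
            proportions=np.full(len(CLASS_LABELS), math.nan),
            n_tiles=0,
        )
    proportions = pooled / n_tiles
    return PatientScore(
        patient_id=patient_id,
        adi=float(proportions[ADI_INDEX]),
        proportions=proportions,
        n_tiles=n_tiles,
    )


def correlate(
    scores: Sequence[float], covariate: Sequence[float], method: str = "spearman"
) -> tuple[float, float]:
    """Correlation between patient scores and a clinical covariate.

    Pairs with a missing value on either side are dropped. Returns
    (rho, p) with the asymptotic p-value; a constant input leaves the
    correlation undefined and returns (nan, nan).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.shape != y.shape:
        raise ValueError("scores and covariate must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    if method == "spearman":
        res = sps.spearmanr(x, y)
    elif method == "pearson":
        res = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue)
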