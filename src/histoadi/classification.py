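"""Nine-class tile classification behind a pluggable model interface.

The original workflow used a transfer-learned VGG19 on the public
100,000-patch nine-class training set; reproducing that is out of scope
here (GPU-scale, external data). What this module preserves is the
*contract*: a model maps any 224x224x3 tile to a probability vector over
the nine canonical classes, and the assigned label is the argmax with a
lowest-index tie-break. The shipped reference model is a multinomial
logistic regression on hand-crafted image features, trained on synthetic
tiles; externally trained models can be dropped in through the same
interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
from skimage.color import rgb2gray
from skimage.feature import graycomatrix, graycoprops
from skimage.filters import sobel
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from histoadi.labels import CLASS_LABELS, LABEL_INDEX, N_CLASSES

FEATURE_NAMES: tuple[str, ...] = (
    "mean_r",
    "mean_g",
    "mean_b",
    "std_r",
    "std_g",
    "std_b",
    "white_fraction",
    "dark_fraction",
    "dark_blob_count",
    "edge_density",
    "glcm_contrast_h",
    "glcm_contrast_v",
    "red_blue_diff",
)

WHITE_LEVEL = 230  # a pixel is "white" when all three channels exceed this
DARK_LEVEL = 120  # "dark" when all three channels are below this
MIN_BLOB_AREA = 10  # px; connected dark components smaller than this are noise


def extract_features(pixels: np.ndarray) -> np.ndarray:
    """Fixed-length feature vector for one 224x224x3 8-bit tile.

    Features: per-channel means and standard deviations (unit scale),
    white-pixel fraction (all channels > 230), dark-pixel fraction and
    dark-blob count (8-connected components of all-channels < 120 with
    area >= 10 px), Sobel edge density, gray-level co-occurrence contrast
    at horizontal and vertical offsets, and the mean red-minus-blue
    difference. Deterministic.
    """
    px = np.asarray(pixels)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 tile, got shape {px.shape}")
    x = px.astype(float)

    means = x.mean(axis=(0, 1)) / 255.0
    stds = x.std(axis=(0, 1)) / 255.0

    white = np.all(px > WHITE_LEVEL, axis=2)
    dark = np.all(px < DARK_LEVEL, axis=2)
    white_fraction = float(white.mean())
    dark_fraction = float(dark.mean())

    n_blobs = 0
    if dark.any():
        components = cc_label(dark, connectivity=2)
        n_blobs = sum(1 for p in regionprops(components) if p.area >= MIN_BLOB_AREA)

    gray = rgb2gray(px)  # float in [0, 1]
    edge_density = float(sobel(gray).mean())

    levels = 32
    quantized = (gray * (levels - 1)).astype(np.uint8)
    glcm = graycomatrix(
        quantized,
        distances=[1],
        angles=[0.0, np.pi / 2],
        levels=levels,
        symmetric=True,
        normed=True,
    )
    contrast_h, contrast_v = graycoprops(glcm, "contrast")[0]

    red_blue = float((x[..., 0] - x[..., 2]).mean() / 255.0)

    return np.array(
        [
            *means,
            *stds,
            white_fraction,
            dark_fraction,
            float(n_blobs),
            edge_density,
            float(contrast_h),
            float(contrast_v),
            red_blue,
        ]
    )


@dataclass
class Prediction:
    """Class probabilities and assigned label for one tile."""

    slide_id: str
    row: int
    col: int
    probabilities: np.ndarray
    label: str = field(init=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (N_CLASSES,):
            raise ValueError(f"probabilities must be a {N_CLASSES}-vector")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be non-negative and sum to 1")
        self.probabilities = p
        self.label = CLASS_LABELS[argmax_label_index(p)]


def argmax_label_index(probabilities: np.ndarray) -> int:
    """Index of the maximum probability; ties go to the lowest index."""
    return int(np.argmax(probabilities))


@dataclass
class ClassifierModel:
    """A fitted tile classifier plus its training metadata."""

    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    coef: np.ndarray  # (9, n_features)
    intercept: np.ndarray  # (9,)
    feature_names: tuple[str, ...] = FEATURE_NAMES
    n_training_tiles: int = 0
    seed: int = 0
    holdout_accuracy: float = float("nan")

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Softmax probabilities for a (n, n_features) feature matrix."""
        z = (features - self.scaler_mean) / self.scaler_scale
        logits = z @ self.coef.T + self.intercept
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        return expl / expl.sum(axis=1, keepdims=True)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "ClassifierModel":
        model = joblib.load(path)
        if not isinstance(model, ClassifierModel):
            raise TypeError(f"{path} does not contain a ClassifierModel")
        return model


def train_reference_classifier(
    tiles: Sequence[np.ndarray],
    labels: Sequence[str],
    seed: int = 0,
    holdout_fraction: float = 0.2,
    min_per_class: int = 20,
) -> ClassifierModel:
    """Fit the reference multinomial-logistic classifier on labeled tiles.

    Requires at least ``min_per_class`` tiles for every one of the nine
    classes. A stratified 20% split is held out and its accuracy stored
    on the returned model. Deterministic under ``seed``.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split
    from sklearn.preprocessing import StandardScaler

    labels = list(labels)
    counts = {lab: labels.count(lab) for lab in CLASS_LABELS}
    missing = [lab for lab, c in counts.items() if c < min_per_class]
    if missing:
        raise ValueError(
            f"need >= {min_per_class} tiles per class; short classes: {missing}"
        )

    features = np.stack([extract_features(t) for t in tiles])
    y = np.array([LABEL_INDEX[lab] for lab in labels])
    x_tr, x_te, y_tr, y_te = train_test_split(
        features, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )

    scaler = StandardScaler().fit(x_tr)
    clf = LogisticRegression(max_iter=2000, C=10.0, random_state=seed)
    clf.fit(scaler.transform(x_tr), y_tr)
    accuracy = float(clf.score(scaler.transform(x_te), y_te))

    return ClassifierModel(
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        coef=clf.coef_.copy(),
        intercept=clf.intercept_.copy(),
        n_training_tiles=len(labels),
        seed=seed,
        holdout_accuracy=accuracy,
    )


def classify_tiles(
    tiles: Iterable, model: ClassifierModel
) -> list[Prediction]:
    """One :class:`Prediction` per tile, input order preserved.

    Accepts :class:`histoadi.tiling.Tile` objects or bare arrays (bare
    arrays get slide_id "" and grid position (-1, -1)).
    """
    tiles = list(tiles)
    if not tiles:
        return []
    arrays, meta = [], []
    for t in tiles:
        if hasattr(t, "pixels"):
            arrays.append(t.pixels)
            meta.append((t.slide_id, t.row, t.col))
        else:
            arrays.append(np.asarray(t))
            meta.append(("", -1, -1))
    features = np.stack([extract_features(a) for a in arrays])
    probs = model.predict_proba(features)
    return [
        Prediction(slide_id=sid, row=r, col=c, probabilities=p)
        for (sid, r, c), p in zip(meta, probs)
    ]
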