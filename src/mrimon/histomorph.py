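"""Supervised per-pixel stain classification and percent-positive-area.

The workflow mirrors interactive histomorphometry tools: annotate some
positive (stained) and negative (counterstain/tissue) pixels, train a
per-pixel classifier on color features, then classify every tissue pixel of
a slide and report iron load as the percentage of positive area relative to
the total tissue area detected.

Features per pixel are the raw RGB channels, two stain-density channels
from color deconvolution with fixed Prussian-blue / nuclear-red unmixing
vectors, and Gaussian-smoothed copies of all five at each requested scale —
stain intensity plus a little spatial context, which is what separates
granular iron deposits from counterstained tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.color import separate_stains
from skimage.filters import gaussian
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier

LABEL_UNLABELED, LABEL_NEGATIVE, LABEL_POSITIVE = 0, 1, 2

#: Optical-density (absorbance) vectors for stain unmixing.  Prussian blue
#: transmits blue (absorbs red/green); nuclear fast red transmits red.
#: The third row is the residual channel (cross product).
_PB = np.array([0.60, 0.66, 0.29])
_NR = np.array([0.17, 0.58, 0.80])
_RES = np.cross(_PB, _NR)
STAIN_MATRIX = np.stack(
    [_PB / np.linalg.norm(_PB), _NR / np.linalg.norm(_NR), _RES / np.linalg.norm(_RES)]
)
_STAIN_INV = np.linalg.inv(STAIN_MATRIX)

DEFAULT_SCALES = (1.0, 2.0)

#: below this many labeled pixels a tree ensemble overfits nothing useful;
#: fall back to a linear discriminant
MIN_PIXELS_FOR_FOREST = 64


def _normalize_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("stain image must be (H, W, 3)")
    if img.max() > 1.0:
        img = img / 255.0
    return np.clip(img, 0.0, 1.0)


def extract_features(image: np.ndarray, scales: tuple[float, ...] = DEFAULT_SCALES) -> np.ndarray:
    """Per-pixel feature stack of shape (H, W, n_features).

    Raw channels (RGB + 2 stain densities) followed by Gaussian-smoothed
    copies at each scale; with no scales the features are the raw channels
    only.  Deterministic.
    """
    img = _normalize_image(image)
    for s in scales:
        if s <= 0:
            raise ValueError("smoothing scales must be > 0")
    density = separate_stains(img, _STAIN_INV)[..., :2]
    base = np.concatenate([img, density], axis=-1)
    layers = [base]
    for s in scales:
        layers.append(gaussian(base, sigma=s, channel_axis=-1, preserve_range=True))
    return np.concatenate(layers, axis=-1)


@dataclass
class PixelModel:
    """Trained per-pixel stain classifier with its feature specification."""

    estimator: object
    scales: tuple[float, ...]
    slide_id: str = ""
    n_labeled: int = 0
    training_accuracy: float = float("nan")
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def predict_positive(self, image: np.ndarray) -> np.ndarray:
        """Boolean positive-class map for a whole slide."""
        feats = extract_features(image, self.scales)
        flat = feats.reshape(-1, feats.shape[-1])
        pred = self.estimator.predict(flat)
        return (pred == LABEL_POSITIVE).reshape(feats.shape[:2])

    def save(self, path: str | Path) -> None:
        """JSON metadata at ``path`` plus a .joblib estimator sidecar."""
        import joblib

        path = Path(path)
        sidecar = path.with_suffix(".joblib")
        joblib.dump(self.estimator, sidecar)
        path.write_text(json.dumps({
            "scales": list(self.scales), "slide_id": self.slide_id,
            "n_labeled": self.n_labeled, "training_accuracy": self.training_accuracy,
            "seed": self.seed, "estimator_file": sidecar.name,
        }, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PixelModel":
        import joblib

        path = Path(path)
        meta = json.loads(path.read_text())
        est = joblib.load(path.parent / meta["estimator_file"])
        return cls(estimator=est, scales=tuple(meta["scales"]),
                   slide_id=meta["slide_id"], n_labeled=meta["n_labeled"],
                   training_accuracy=meta["training_accuracy"], seed=meta["seed"])


def train_pixel_model(
    image: np.ndarray,
    annotations: np.ndarray,
    *,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    seed: int = 0,
    slide_id: str = "",
    n_estimators: int = 50,
) -> PixelModel:
    """Train a classifier from annotated pixels of one slide.

    ``annotations`` is an integer map: 0 unlabeled, 1 negative, 2 positive;
    both classes must be present.  Labeled pixels are gathered in canonical
    (flat-index) order before fitting, so shuffled annotation order cannot
    change the model.  Small training sets fall back from a seeded random
    forest to a linear discriminant.
    """
    ann = np.asarray(annotations)
    if ann.shape != np.asarray(image).shape[:2]:
        raise ValueError("annotation mask must match image height/width")
    labeled = np.flatnonzero(ann.ravel() != LABEL_UNLABELED)
    labeled.sort()
    y = ann.ravel()[labeled]
    classes = np.unique(y)
    if not (LABEL_NEGATIVE in classes and LABEL_POSITIVE in classes):
        raise ValueError("training needs at least one positive and one negative pixel")

    feats = extract_features(image, scales)
    X = feats.reshape(-1, feats.shape[-1])[labeled]
    if np.allclose(X[y == LABEL_POSITIVE].mean(axis=0), X[y == LABEL_NEGATIVE].mean(axis=0)) and np.allclose(X.std(axis=0), 0.0):
        raise ValueError("classes are identical in feature space: unlearnable")

    if labeled.size < MIN_PIXELS_FOR_FOREST:
        est = LinearDiscriminantAnalysis()
    else:
        est = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1,
            min_samples_leaf=2,
        )
    est.fit(X, y)
    acc = float((est.predict(X) == y).mean())
    return PixelModel(
        estimator=est, scales=tuple(scales), slide_id=slide_id,
        n_labeled=int(labeled.size), training_accuracy=acc, seed=seed,
    )


def read_stain_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG slide into a float RGB array in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        raw = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        raw = iio.imread(str(path))
    if raw.ndim == 3 and raw.shape[2] > 3:
        raw = raw[..., :3]  # drop alpha
    return _normalize_image(raw)


def read_annotation_mask(path: str | Path) -> np.ndarray:
    """Read an indexed PNG annotation mask (0 unlabeled, 1 negative, 2 positive)."""
    import imageio.v3 as iio

    ann = np.asarray(iio.imread(str(path)))
    if ann.ndim == 3:
        ann = ann[..., 0]
    return ann.astype(np.int32)


@dataclass
class IronLoadResult:
    slide_id: str
    positive_area_percent: float
    n_positive: int
    n_tissue: int


def tissue_mask_from_luminance(image: np.ndarray, threshold: float = 0.95) -> np.ndarray:
    """Tissue = pixels darker than a luminance threshold (background is
    near-white glass on a scanned slide)."""
    img = _normalize_image(image)
    lum = img @ np.array([0.2126, 0.7152, 0.0722])
    return lum < threshold


def iron_load(
    image: np.ndarray,
    model: PixelModel,
    tissue_mask: np.ndarray | None = None,
) -> IronLoadResult:
    """Percent positive area over the tissue pixels of one slide."""
    if tissue_mask is None:
        tissue_mask = tissue_mask_from_luminance(image)
    tissue_mask = np.asarray(tissue_mask, bool)
    if not tissue_mask.any():
        raise ValueError("empty tissue mask")
    positive = model.predict_positive(image)
    n_tissue = int(tissue_mask.sum())
    n_pos = int((positive & tissue_mask).sum())
    return IronLoadResult(
        slide_id=model.slide_id,
        positive_area_percent=100.0 * n_pos / n_tissue,
        n_positive=n_pos,
        n_tissue=n_tissue,
    )
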