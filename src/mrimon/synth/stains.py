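"""Synthetic two-color stained slides with a known positive-area fraction.

Emulates an iron-stained tissue section: a configurable fraction of pixels
is "positive" (stain-laden, e.g. Prussian-blue granules) and the rest
"negative" (counterstained tissue).  Pixel colors are drawn around the two
class colors with Gaussian jitter, and the exact ground-truth mask is
returned, so a pixel classifier's percent-positive-area estimate can be
scored against the fraction that generated the slide.
"""

from __future__ import annotations

import numpy as np

#: Default class colors (RGB in [0, 1]): dark Prussian blue vs. pale
#: nuclear-red counterstain.
POSITIVE_COLOR = (0.10, 0.18, 0.48)
NEGATIVE_COLOR = (0.85, 0.62, 0.66)


def generate_stain_image(
    width: int,
    height: int,
    positive_fraction: float,
    *,
    positive_color: tuple[float, float, float] = POSITIVE_COLOR,
    negative_color: tuple[float, float, float] = NEGATIVE_COLOR,
    color_jitter_sd: float = 0.03,
    clump_scale: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a (height, width, 3) float RGB slide and its ground-truth mask.

    Exactly ``round(positive_fraction * width * height)`` pixels are
    positive (within one pixel's rounding of the requested fraction).  With
    ``clump_scale > 0`` positive pixels are placed preferentially where a
    smoothed random field is large, giving granule-like clusters instead of
    salt-and-pepper; the count is unchanged.

    Returns ``(image, mask)`` with ``mask`` boolean, True on positives.
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must be in [0, 1]")
    if width <= 0 or height <= 0:
        raise ValueError("width and height must be positive")
    pos = np.asarray(positive_color, float)
    neg = np.asarray(negative_color, float)
    n_total = width * height
    n_pos = int(round(positive_fraction * n_total))
    if (
        color_jitter_sd == 0
        and 0 < n_pos < n_total
        and np.allclose(pos, neg)
    ):
        raise ValueError(
            "identical class colors with zero jitter are unlearnable"
        )

    rng = np.random.default_rng(seed)
    mask = np.zeros(n_total, dtype=bool)
    if n_pos:
        if clump_scale > 0:
            from scipy.ndimage import gaussian_filter

            field = gaussian_filter(
                rng.standard_normal((height, width)), clump_scale
            ).ravel()
            order = np.argsort(-field, kind="stable")
            mask[order[:n_pos]] = True
        else:
            mask[rng.choice(n_total, size=n_pos, replace=False)] = True
    mask = mask.reshape(height, width)

    image = np.where(mask[..., None], pos, neg).astype(float)
    if color_jitter_sd > 0:
        image = image + rng.normal(0.0, color_jitter_sd, image.shape)
        image = np.clip(image, 0.0, 1.0)
    return image, mask
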