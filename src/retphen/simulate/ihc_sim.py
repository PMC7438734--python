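"""Synthetic DAB/haematoxylin section images with exact stain-area truth.

Images are flat-colour: background pixels take a haematoxylin-like blue and
stained pixels a DAB brown inside the analysis gamut.  The stained mask is
built from round blobs around random centres but trimmed/extended to an
exact integer pixel count, so the programmed area fraction is recoverable
to the pixel by thresholding.  Texture, lighting gradients and partial-
volume colour mixing of real sections are intentionally absent.
"""

from __future__ import annotations

import numpy as np

__all__ = ["simulate_ihc_image"]

DAB_RGB = (150, 90, 40)
HAEMATOXYLIN_RGB = (130, 120, 180)


def simulate_ihc_image(
    area_fraction: float,
    seed_or_rng=0,
    shape: tuple[int, int] = (128, 128),
    n_blobs: int = 6,
    stain_rgb: tuple = DAB_RGB,
    background_rgb: tuple = HAEMATOXYLIN_RGB,
) -> tuple[np.ndarray, int]:
    """RGB uint8 image with exactly round(area_fraction·H·W) stained pixels.

    Returns (image, stained_pixel_count).
    """
    if not (0.0 <= area_fraction <= 1.0):
        raise ValueError("area fraction must lie in [0, 1]")
    h, w = shape
    total = h * w
    target = int(round(area_fraction * total))
    if target > total:
        raise ValueError("infeasible blob packing: fraction exceeds image")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[...] = np.asarray(background_rgb, dtype=np.uint8)
    if target > 0:
        centers = rng.uniform(0, [h, w], size=(max(1, n_blobs), 2))
        yy, xx = np.mgrid[0:h, 0:w]
        pts = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(float)
        # distance to nearest blob centre; the `target` closest pixels stain,
        # giving round blobs with an exact count
        d = np.min(
            np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2), axis=1
        )
        order = np.argsort(d, kind="stable")[:target]
        mask = np.zeros(total, dtype=bool)
        mask[order] = True
        img.reshape(-1, 3)[mask] = np.asarray(stain_rgb, dtype=np.uint8)
    return img, target
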