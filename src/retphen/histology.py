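"""DAB immunohistochemistry quantification by HSI thresholding.

Amyloid burden on DAB/haematoxylin sections is quantified as percent area:
pixels whose hue–saturation–intensity coordinates fall inside a fixed gamut
(one threshold per magnification, applied to every image) are counted as
stained, and reported as a percentage of all pixels in the image.  Three
sections per location per animal are averaged into one per-animal value, and
burden is regressed on age by ordinary least squares.

HSI convention (bi-hexcone / Gonzalez-Woods):

    I = (R + G + B) / 3
    S = 1 - min(R, G, B) / I             (0 for black)
    H = acos( ((R-G) + (R-B)) / 2 / sqrt((R-G)^2 + (R-B)(G-B)) ),
        reflected to 360 - H when B > G; undefined (reported 0) when S = 0.

Hue is degrees in [0, 360); saturation and intensity are in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = [
    "HsiThreshold",
    "AreaResult",
    "rgb_to_hsi",
    "threshold_stain",
    "aggregate_animal",
    "regress_burden_on_age",
    "percent_area",
]


@dataclass(frozen=True)
class HsiThreshold:
    """In-gamut intervals; the hue interval may wrap through 360° → 0°."""

    hue: tuple[float, float] = (10.0, 50.0)  # degrees, circular
    saturation: tuple[float, float] = (0.15, 1.0)
    intensity: tuple[float, float] = (0.0, 0.85)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("saturation", self.saturation),
            ("intensity", self.intensity),
        ):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} interval must satisfy 0 <= lo <= hi <= 1")
        h0, h1 = self.hue
        if not (0.0 <= h0 < 360.0 and 0.0 <= h1 < 360.0):
            raise ValueError("hue bounds must lie in [0, 360)")


@dataclass(frozen=True)
class AreaResult:
    """Stained-pixel count as a fraction of the image."""

    stained_pixels: int
    total_pixels: int

    @property
    def percent_area(self) -> float:
        return 100.0 * self.stained_pixels / self.total_pixels


def percent_area(stained: int, total: int) -> float:
    """Stained count over total, as a percentage."""
    return AreaResult(stained, total).percent_area


def _as_float_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an RGB image array (H, W, 3)")
    img = img[..., :3].astype(float)
    if img.max() > 1.0:
        img = img / 255.0
    return img


def rgb_to_hsi(img: np.ndarray):
    """Vectorized HSI transform.

    Returns (hue_deg, saturation, intensity, hue_defined); hue is 0 with
    ``hue_defined`` False for achromatic pixels.
    """
    rgb = _as_float_rgb(img)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    i = (r + g + b) / 3.0
    mn = np.minimum(np.minimum(r, g), b)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(i > 0, 1.0 - mn / i, 0.0)
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.degrees(np.arccos(np.clip(np.where(den > 0, num / den, 1.0), -1, 1)))
    h = np.where(b > g, 360.0 - theta, theta)
    defined = s > 0
    h = np.where(defined, h % 360.0, 0.0)
    return h, s, i, defined


def _hue_in(h: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    lo, hi = interval
    if lo <= hi:
        return (h >= lo) & (h <= hi)
    return (h >= lo) | (h <= hi)  # wraps through 360 → 0


def threshold_stain(img: np.ndarray, thr: HsiThreshold) -> AreaResult:
    """Count pixels inside the HSI gamut; metadata-blind by construction."""
    h, s, i, defined = rgb_to_hsi(img)
    mask = (
        defined
        & _hue_in(h, thr.hue)
        & (s >= thr.saturation[0])
        & (s <= thr.saturation[1])
        & (i >= thr.intensity[0])
        & (i <= thr.intensity[1])
    )
    return AreaResult(int(mask.sum()), int(mask.size))


def aggregate_animal(results, n_sections: int = 3) -> float:
    """Mean percent area over the per-animal sections (default exactly 3)."""
    vals = [r.percent_area if isinstance(r, AreaResult) else float(r) for r in results]
    if len(vals) != n_sections:
        raise ValueError(
            f"expected {n_sections} section results per animal, got {len(vals)}"
        )
    return float(np.mean(vals))


def regress_burden_on_age(points) -> dict:
    """OLS of percent stain area on age (months).

    ``points`` is an iterable of (age_months, percent_area).  Returns slope,
    intercept, R² and the two-sided p-value for the slope.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (age, percent) points")
    if np.unique(pts[:, 0]).size < 2:
        raise ValueError("need at least 2 distinct ages")
    x = sm.add_constant(pts[:, 0])
    fit = sm.OLS(pts[:, 1], x).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r_squared": float(fit.rsquared),
        "p_value": float(fit.pvalues[1]),
        "n": int(pts.shape[0]),
    }
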