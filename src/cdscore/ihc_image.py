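"""Dual-marker IHC image analysis: stain detection and vessel distances.

DAB-stained marker regions (brown) are segmented by moment-preserving
("Moments") histogram thresholding of an inverted grayscale image, so the
dark stain is high-valued.  Hematoxylin-stained nuclei fall inside the
thresholded area but are distinctly blue, so pixels with blue intensity
strictly greater than red are removed.  For every surviving marker pixel
the Euclidean distance (pixel center to pixel center) to the nearest
vessel pixel is measured, and the two markers' distance distributions are
compared with a two-sided Wilcoxon rank-sum test.  Staining burden per
tumor is summarized by the H-score, 3x%strong + 2x%moderate + %weak,
ranging 0-300.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import distance_transform_edt


def to_gray(rgb: np.ndarray) -> np.ndarray:
    """Inverted grayscale (255 - channel mean): stain is dark, so high-valued."""
    return 255.0 - np.asarray(rgb, dtype=float).mean(axis=2)


def moments_threshold(gray: np.ndarray) -> tuple[int, np.ndarray]:
    """Moment-preserving (Tsai) threshold on a 256-bin histogram.

    The histogram's first three gray-level moments determine the two
    representative levels of an ideal bilevel image and the fraction ``p0``
    of pixels belonging to the lower level.  The threshold is placed just
    above the gray level whose cumulative histogram fraction is closest to
    ``p0`` (ties toward the lower level); pixels ``>= threshold`` are
    foreground.  Returns ``(threshold, mask)``.
    """
    gray = np.asarray(gray)
    flat = np.clip(np.round(gray), 0, 255).astype(int).ravel()
    if flat.max() == flat.min():
        raise ValueError("constant image: threshold undefined")
    hist = np.bincount(flat, minlength=256).astype(float)
    p = hist / hist.sum()
    levels = np.arange(256, dtype=float)
    m1 = (p * levels).sum()
    m2 = (p * levels ** 2).sum()
    m3 = (p * levels ** 3).sum()
    cd = m2 - m1 ** 2
    c0 = (-m2 ** 2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 ** 2 - 4.0 * c0, 0.0)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    p0 = (z1 - m1) / (z1 - z0) if z1 != z0 else 0.5
    cum = np.cumsum(p)
    level = int(np.argmin(np.abs(cum - p0)))  # argmin takes the lowest tie
    threshold = level + 1
    mask = np.round(gray) >= threshold
    return threshold, mask


def remove_blue_pixels(rgb: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Drop mask pixels whose blue intensity strictly exceeds red.

    Hematoxylin-stained nuclei are dark blue and survive the intensity
    threshold; DAB is brown (R > B), so the strict ``B > R`` filter removes
    nuclei while keeping marker signal.  Idempotent.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    return mask & ~(rgb[..., 2] > rgb[..., 0])


def segment_marker(rgb: np.ndarray) -> tuple[int, np.ndarray]:
    """Full stain segmentation: Moments threshold then blue-pixel removal."""
    threshold, mask = moments_threshold(to_gray(rgb))
    return threshold, remove_blue_pixels(rgb, mask)


@dataclass
class DistanceTable:
    marker: str
    distances: np.ndarray     # micrometres, one per marker-positive pixel

    @property
    def median(self) -> float:
        return float(np.median(self.distances)) if len(self.distances) else float("nan")

    @property
    def iqr(self) -> tuple[float, float]:
        if not len(self.distances):
            return (float("nan"), float("nan"))
        q1, q3 = np.percentile(self.distances, [25, 75])
        return (float(q1), float(q3))


def distance_to_vessel(marker_mask: np.ndarray, vessel_mask: np.ndarray,
                       pixel_size: float = 1.0,
                       marker: str = "marker") -> DistanceTable:
    """Distance from each marker-positive pixel to the nearest vessel pixel.

    Exact Euclidean, pixel center to pixel center, scaled by ``pixel_size``
    (micrometres per pixel); equals a brute-force nearest-neighbor scan.
    """
    vessel_mask = np.asarray(vessel_mask, bool)
    marker_mask = np.asarray(marker_mask, bool)
    if not vessel_mask.any():
        raise ValueError("vessel mask is empty")
    if not marker_mask.any():
        return DistanceTable(marker=marker, distances=np.empty(0))
    dist = distance_transform_edt(~vessel_mask)
    return DistanceTable(marker=marker,
                         distances=dist[marker_mask] * float(pixel_size))


def compare_marker_distances(d1: DistanceTable, d2: DistanceTable
                             ) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two distance distributions.

    Exact enumeration when both samples have n <= 8 and no cross-sample
    ties; otherwise the tie-corrected normal approximation.  Returns
    ``(U statistic, p)``.
    """
    a, b = np.asarray(d1.distances), np.asarray(d2.distances)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both distance tables must be non-empty")
    exact = len(a) <= 8 and len(b) <= 8 and len(np.unique(np.r_[a, b])) == len(a) + len(b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def h_score(pct_strong: float, pct_moderate: float, pct_weak: float) -> float:
    """H-score = 3x%strong + 2x%moderate + %weak, in [0, 300]."""
    pcts = (pct_strong, pct_moderate, pct_weak)
    if any(p < 0 for p in pcts):
        raise ValueError("percentages must be non-negative")
    if sum(pcts) > 100 + 1e-9:
        raise ValueError("stained percentages sum above 100")
    return 3.0 * pct_strong + 2.0 * pct_moderate + 1.0 * pct_weak
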