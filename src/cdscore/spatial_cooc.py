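"""Radial co-occurrence of a target cell category around anchor cells.

For each distance annulus the statistic is the conditional frequency of
the target category among all non-anchor points lying within that annulus
of at least one anchor, divided by the target's global frequency among
non-anchor points.  A ratio above 1 means the target is enriched near the
anchors at that distance (e.g. myCAFs around micropapillary tumor cells);
a ratio near 1 means spatial independence.

Points are counted once per annulus regardless of how many anchors they
neighbor (presence semantics); a pair-counting mode weighting each
point-anchor pair is available by flag.  Distance units are whatever the
coordinates are in — pixels or micrometres — and are caller-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class CoocCurve:
    radii: np.ndarray            # bin edges, length n_bins + 1
    ratio: np.ndarray            # enrichment per annulus, NaN when undefined
    target_counts: np.ndarray    # target points per annulus
    total_counts: np.ndarray     # all non-anchor points per annulus

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_lo": self.radii[:-1], "r_hi": self.radii[1:],
                             "ratio": self.ratio,
                             "n_target": self.target_counts,
                             "n_total": self.total_counts})


def default_radii(points: pd.DataFrame, anchor_cat: str,
                  n_bins: int = 10) -> np.ndarray:
    """Log-spaced bin edges from 0 up to the 90th percentile of
    anchor-to-point distances."""
    anchors = points.loc[points.label == anchor_cat, ["x", "y"]].to_numpy()
    others = points.loc[points.label != anchor_cat, ["x", "y"]].to_numpy()
    d, _ = cKDTree(anchors).query(others, k=1)
    hi = max(float(np.percentile(d, 90)), np.finfo(float).eps)
    inner = np.geomspace(hi / n_bins, hi, n_bins)
    return np.concatenate([[0.0], inner])


def co_occurrence(points: pd.DataFrame, anchor_cat: str, target_cat: str,
                  radii: np.ndarray | None = None,
                  pair_counting: bool = False) -> CoocCurve:
    """Co-occurrence ratio of ``target_cat`` around ``anchor_cat`` per annulus.

    ``radii`` are strictly increasing bin edges starting at 0 (default: 10
    log-spaced annuli up to the 90th percentile of anchor-point nearest
    distances).  Annuli containing no points are flagged NaN, never
    interpolated.  The curve is invariant under global isometries of the
    coordinates.
    """
    labels = points.label.to_numpy()
    present = set(labels)
    if anchor_cat not in present:
        raise ValueError(f"no anchor points of category {anchor_cat!r}")
    if target_cat not in present:
        raise ValueError(f"no target points of category {target_cat!r}")
    if radii is None:
        radii = default_radii(points, anchor_cat)
    radii = np.asarray(radii, dtype=float)
    if radii[0] != 0 or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must increase strictly from 0")

    anchors = points.loc[labels == anchor_cat, ["x", "y"]].to_numpy()
    rest = points.loc[labels != anchor_cat]
    xy = rest[["x", "y"]].to_numpy()
    is_target = (rest.label == target_cat).to_numpy()
    p_global = is_target.mean()

    tree = cKDTree(anchors)
    # anchors within distance <= r of each point, cumulative over edges
    cum = np.stack([tree.query_ball_point(xy, r, return_length=True)
                    for r in radii])
    n_bins = len(radii) - 1
    ratio = np.full(n_bins, np.nan)
    n_target = np.zeros(n_bins, dtype=float)
    n_total = np.zeros(n_bins, dtype=float)
    for i in range(n_bins):
        # within annulus (r_lo, r_hi]: gained at least one anchor neighbor
        weight = (cum[i + 1] - cum[i]) if pair_counting else (cum[i + 1] > cum[i])
        w = weight.astype(float)
        n_total[i] = w.sum()
        n_target[i] = w[is_target].sum()
        if n_total[i] > 0 and p_global > 0:
            ratio[i] = (n_target[i] / n_total[i]) / p_global
    return CoocCurve(radii=radii, ratio=ratio,
                     target_counts=n_target, total_counts=n_total)
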