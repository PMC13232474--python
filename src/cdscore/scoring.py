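"""Signature scoring and subtype classification rules.

Bulk samples are scored with a single-sample rank-walk enrichment
statistic (ssGSEA-style): genes are ranked by expression within each
sample and a running sum accumulates weighted increments at signature
genes and a constant decrement elsewhere; the score is the area under the
running sum.  The published decision rules operate on these scores:

* bulk quartile rule — rank samples by ``delta = score_LLI - score_BL``;
  the top quartile is called LLI-like, the bottom quartile BL, the rest
  intermediate;
* bulk sign rule — ``delta > 0`` is LLI-like, ``delta < 0`` BL-like
  (``delta == 0`` is left intermediate: both published inequalities are
  strict);
* single-cell quantile rule — a cell is labelled with the one subtype
  whose within-class score threshold (default the 0.75 quantile) it meets
  exclusively; cells meeting zero or several thresholds are unidentified.

Cell populations in the microenvironment are typed by marker expression:
CAF subtypes by argmax of z-scored canonical markers, macrophage
polarization by M1/M2 module scores (mean expression of the set minus
mean of expression-matched control genes).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def ss_enrichment_score(expr: pd.DataFrame, gene_set: Sequence[str],
                        alpha: float = 0.25) -> pd.Series:
    """Single-sample rank-walk enrichment score per sample (column).

    Within each sample genes are ordered by decreasing expression (ties by
    gene_id); walking down the list, set members add a weight
    ``rank^alpha`` (rank N for the top gene) and non-members subtract
    ``1/(N - k)``.  Member weights are normalized by the weight mass of the
    ideal placement (the k top ranks), a placement-independent constant:
    this bounds the score by its analytic maximum and makes it strictly
    monotone under rank improvement of any member.  The score is the mean
    of the running sum over all positions.
    """
    genes = expr.index
    in_set = genes.isin(set(gene_set))
    if not in_set.any():
        missing = sorted(set(gene_set) - set(genes))
        raise ValueError(f"gene set absent from matrix: {missing}")
    n = len(genes)
    k = int(in_set.sum())
    scores = {}
    # order by (-expression, gene_id): stable sort on gene_id then expression
    gene_order = np.argsort(genes.to_numpy())
    rank_weight = (n - np.arange(n, dtype=float)) ** alpha
    w_ideal = rank_weight[:k].sum()
    for col in expr.columns:
        x = expr[col].to_numpy(dtype=float)[gene_order]
        order = gene_order[np.argsort(-x, kind="mergesort")]
        member = in_set[order]
        inc = np.where(member, rank_weight / w_ideal, 0.0)
        dec = np.zeros(n)
        if n > k:
            dec[~member] = 1.0 / (n - k)
        walk = np.cumsum(inc - dec)
        scores[col] = walk.sum() / n
    return pd.Series(scores, name="es")


def module_score(cells: pd.DataFrame, gene_set: Sequence[str],
                 n_bins: int = 25, n_ctrl: int = 100,
                 seed: int | None = 0) -> pd.Series:
    """Mean set expression minus expression-matched control mean, per cell.

    Genes are cut into ``n_bins`` equal-frequency bins of average
    expression across cells; each set gene draws ``n_ctrl`` control genes
    (with replacement, seeded) from the non-set genes of its bin, falling
    back to the nearest non-empty bin.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    gene_set = [g for g in gene_set]
    missing = set(gene_set) - set(cells.index)
    if missing:
        raise ValueError(f"gene set absent from matrix: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    avg = cells.mean(axis=1)
    # equal-frequency binning via average ranks, deterministic under ties
    ranks = avg.rank(method="first")
    bin_of = np.minimum(((ranks - 1) / len(avg) * n_bins).astype(int), n_bins - 1)
    bin_of = pd.Series(bin_of.to_numpy(), index=cells.index)

    in_set = cells.index.isin(gene_set)
    pool_by_bin = {b: cells.index[(bin_of == b) & ~in_set]
                   for b in range(n_bins)}
    ctrl_genes: list[str] = []
    for g in gene_set:
        b = int(bin_of[g])
        pool = pool_by_bin[b]
        if len(pool) == 0:  # nearest non-empty bin
            for d in range(1, n_bins):
                for bb in (b - d, b + d):
                    if 0 <= bb < n_bins and len(pool_by_bin[bb]):
                        pool = pool_by_bin[bb]
                        break
                if len(pool):
                    break
        if len(pool) == 0:
            raise ValueError("no non-set control genes available")
        ctrl_genes.extend(pool[rng.integers(0, len(pool), n_ctrl)])
    set_mean = cells.loc[gene_set].mean(axis=0)
    ctrl_mean = cells.loc[ctrl_genes].mean(axis=0)
    return (set_mean - ctrl_mean).rename("module_score")


def score_table(scores: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Assemble per-unit subtype scores and ``delta = score_LLI - score_BL``."""
    df = pd.DataFrame({st: s for st, s in scores.items()})
    if {"LLI", "BL"} <= set(df.columns):
        df["delta"] = df["LLI"] - df["BL"]
    return df


def classify_bulk_quartile(scores: pd.DataFrame) -> pd.Series:
    """Quartile rule on delta: top quartile LLI-like, bottom quartile BL.

    Quartile size is ``ceil(N/4)``; rank ties break deterministically by
    unit id.  Requires at least 4 samples.
    """
    if len(scores) < 4:
        raise ValueError("need at least 4 samples for the quartile rule")
    order = scores.assign(_unit=scores.index).sort_values(
        ["delta", "_unit"], ascending=[False, True], kind="mergesort").index
    nq = -(-len(order) // 4)
    labels = pd.Series("intermediate", index=scores.index, name="label")
    labels[order[:nq]] = "LLI-like"
    labels[order[-nq:]] = "BL"
    return labels


def classify_bulk_sign(scores: pd.DataFrame) -> pd.Series:
    """Sign rule on delta: > 0 LLI-like, < 0 BL-like, 0 intermediate."""
    delta = scores["delta"]
    labels = pd.Series("intermediate", index=scores.index, name="label")
    labels[delta > 0] = "LLI-like"
    labels[delta < 0] = "BL-like"
    return labels


def classify_cells_quantile(scores: pd.DataFrame, q: float = 0.75,
                            classes: Sequence[str] = ("LLI", "BL", "MP")
                            ) -> pd.Series:
    """Exclusive quantile rule for single cells.

    Each class's threshold is the ``q``-quantile (linear interpolation) of
    its scores across cells; a cell gets class C iff it meets C's threshold
    and no other class's.  Cells meeting zero or >= 2 thresholds are
    ``unidentified``.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    if len(scores) < 4:
        raise ValueError("need at least 4 cells")
    classes = [c for c in classes if c in scores.columns]
    thr = {c: float(np.quantile(scores[c].to_numpy(), q)) for c in classes}
    met = pd.DataFrame({c: scores[c] >= thr[c] for c in classes})
    n_met = met.sum(axis=1)
    labels = pd.Series("unidentified", index=scores.index, name="label")
    single = n_met == 1
    naming = {"LLI": "LLI-like", "BL": "BL-like", "MP": "MP"}
    labels[single] = met[single].idxmax(axis=1).map(lambda c: naming.get(c, c))
    return labels


def assign_marker_subtype(cells: pd.DataFrame,
                          marker_map: Mapping[str, Sequence[str]]) -> pd.Series:
    """Argmax of mean z-scored marker expression; ties and all-zero cells
    are ``unassigned``."""
    all_markers = [g for gs in marker_map.values() for g in gs]
    missing = set(all_markers) - set(cells.index)
    if missing:
        raise ValueError(f"marker genes absent: {sorted(missing)}")
    x = cells.loc[all_markers]
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=0).replace(0, 1.0)
    z = x.sub(mu, axis=0).div(sd, axis=0)
    means = pd.DataFrame({st: z.loc[list(gs)].mean(axis=0)
                          for st, gs in marker_map.items()})
    best = means.max(axis=1)
    is_tie = (means.eq(best, axis=0).sum(axis=1) > 1)
    labels = means.idxmax(axis=1)
    labels[is_tie] = "unassigned"
    labels[(x != 0).sum(axis=0) == 0] = "unassigned"
    return labels.rename("label")


def m1_m2_scores(cells: pd.DataFrame, m1_set: Sequence[str],
                 m2_set: Sequence[str], seed: int | None = 0,
                 sample_of: Mapping[str, str] | None = None):
    """M1/M2 polarization module scores and the per-sample M2:M1 ratio.

    The ratio is ``#cells with M2 > M1`` over ``#cells with M1 > M2``
    (NaN-flagged when the denominator is zero).  When two samples are
    given, they are compared by rank-sum on per-cell ``M2 - M1``.
    Returns ``(per_cell_table, per_sample_ratio)``.
    """
    if set(m1_set) & set(m2_set):
        raise ValueError("M1 and M2 sets must be disjoint")
    m1 = module_score(cells, m1_set, seed=seed)
    m2 = module_score(cells, m2_set, seed=seed)
    per_cell = pd.DataFrame({"M1": m1, "M2": m2, "diff": m2 - m1})
    if sample_of is None:
        sample_of = {c: "all" for c in cells.columns}
    per_cell["sample"] = pd.Series(dict(sample_of)).reindex(per_cell.index)
    ratios = {}
    for s, grp in per_cell.groupby("sample"):
        n_m2 = int((grp["diff"] > 0).sum())
        n_m1 = int((grp["diff"] < 0).sum())
        ratios[s] = n_m2 / n_m1 if n_m1 > 0 else float("nan")
    return per_cell, pd.Series(ratios, name="m2_m1_ratio")


def compare_m1m2_between_samples(per_cell: pd.DataFrame, sample_a: str,
                                 sample_b: str) -> tuple[float, float]:
    """Rank-sum comparison of per-cell (M2 - M1) between two samples."""
    a = per_cell.loc[per_cell["sample"] == sample_a, "diff"]
    b = per_cell.loc[per_cell["sample"] == sample_b, "diff"]
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
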