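"""Normalization, clustering and differential testing of peak count matrices.

The workflow mirrors a standard differential-binding analysis of H3K27ac
ChIP-seq read densities: sequencing depth is absorbed by total-count size
factors, sample relationships are summarized by Spearman-correlation
distance with average-linkage clustering, cluster separation is tested by
PERMANOVA, and per-peak (or per-gene) differences are assessed with a
negative-binomial Wald test.  Features are called differential at
``padj <= 0.05`` and ``|log2FC| > 0.5``.

The NB test estimates a per-feature dispersion by method of moments pooled
across the two groups, with no shrinkage; it is validated by type-I-error
and power simulations rather than by equivalence to any external package.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


def normalize_counts(counts: pd.DataFrame, log2: bool = False) -> pd.DataFrame:
    """Divide each sample by its total-count size factor.

    The size factor is ``s_j = total_j / geometric mean of totals`` so the
    factors multiply to one; with ``log2`` the result is
    ``log2(normalized + 1)``.
    """
    totals = counts.sum(axis=0).astype(float)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    size_factors = totals / np.exp(np.mean(np.log(totals)))
    norm = counts / size_factors
    return np.log2(norm + 1.0) if log2 else norm


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: pd.Series
    distance: pd.DataFrame      # 1 - Spearman rho, samples x samples
    permanova_f: float | None = None
    permanova_p: float | None = None


def spearman_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """1 - Spearman correlation between samples (columns); ties get average ranks."""
    x = matrix.to_numpy(dtype=float)
    if np.any(np.ptp(x, axis=0) == 0):
        bad = matrix.columns[np.ptp(x, axis=0) == 0]
        raise ValueError(f"constant sample vector(s): {list(bad)}")
    rho = stats.spearmanr(x).statistic
    rho = np.atleast_2d(rho)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def correlation_clustering(matrix: pd.DataFrame, k: int) -> ClusterResult:
    """Average-linkage tree on Spearman distance, cut to ``k`` clusters."""
    if matrix.shape[1] < k:
        raise ValueError("fewer samples than requested clusters")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 features")
    d = spearman_distance(matrix)
    z = hierarchy.linkage(squareform(d.to_numpy(), checks=False), method="average")
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return ClusterResult(linkage=z,
                         labels=pd.Series(labels, index=matrix.columns, name="cluster"),
                         distance=d)


def _permanova_f(d2: np.ndarray, onehot: np.ndarray, n_g: np.ndarray) -> np.ndarray:
    """F statistics for one-hot label matrices of shape (..., N, groups)."""
    n = d2.shape[0]
    a = n_g.shape[-1]
    ss_total = d2.sum() / (2.0 * n)
    # within-group pair sums: sum_g (z_g' D2 z_g) / n_g, pairs counted twice
    zdz = np.einsum("...ig,ij,...jg->...g", onehot, d2, onehot)
    ss_within = (zdz / n_g).sum(axis=-1) / 2.0
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


def permanova(distance: pd.DataFrame | np.ndarray, labels, n_perm: int = 999,
              seed: int | None = 0, exhaustive: bool = False) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    ``F = ((SS_total - SS_within)/(a-1)) / (SS_within/(N-a))`` with sums of
    squared distances; the p-value is ``(1 + #{F_perm >= F_obs}) / (n_perm + 1)``
    over seeded free label permutations, or the exact fraction over all
    distinct permutations when ``exhaustive``.
    """
    d = distance.to_numpy(dtype=float) if isinstance(distance, pd.DataFrame) else np.asarray(distance, float)
    labels = np.asarray(pd.Series(labels).astype("category").cat.codes)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix does not match labels")
    if not np.any(d > 0):
        raise ValueError("degenerate distance matrix (all zeros): F undefined")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    d2 = d ** 2
    a = len(groups)

    def onehot(lab: np.ndarray) -> np.ndarray:
        z = np.zeros(lab.shape + (a,))
        np.put_along_axis(z, lab[..., None], 1.0, axis=-1)
        return z

    f_obs = float(_permanova_f(d2, onehot(labels), counts.astype(float)))

    if exhaustive:
        perms = np.array(list(itertools.permutations(labels)))
        f_perm = _permanova_f(d2, onehot(perms), counts.astype(float))
        p = float(np.mean(f_perm >= f_obs - 1e-12))
        return f_obs, p

    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    f_perm = _permanova_f(d2, onehot(labels[idx]), counts.astype(float))
    p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (n_perm + 1.0)
    return f_obs, float(p)


def pca(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples (columns) on the eigenvectors of the feature-centered
    covariance; returns (coordinates, variance fractions summing to 1)."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    coords = (vt.T * s)
    var = s ** 2
    frac = var / var.sum() if var.sum() > 0 else var
    ncomp = min(matrix.shape[1], matrix.shape[0])
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (pd.DataFrame(coords, index=matrix.columns, columns=cols),
            frac[:ncomp])


def nb_differential(counts: pd.DataFrame, group_a, group_b) -> pd.DataFrame:
    """Negative-binomial Wald test of group A vs group B per feature.

    Counts are size-factor normalized (total-count factors over the tested
    samples); ``log2fc = log2((mean_a + 0.5)/(mean_b + 0.5))``; the standard
    error comes from the delta method on the NB variance ``m + phi m^2``
    with a pooled method-of-moments dispersion floored at 1e-8.  Returns a
    table (feature, log2fc, p, padj, mean_a, mean_b) with BH-adjusted p.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    sub = counts[group_a + group_b]
    norm = normalize_counts(sub)
    xa = norm[group_a].to_numpy(dtype=float)
    xb = norm[group_b].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        phi_a = (va - ma) / ma ** 2
        phi_b = (vb - mb) / mb ** 2
    phi_a[~np.isfinite(phi_a)] = 0.0
    phi_b[~np.isfinite(phi_b)] = 0.0
    phi = ((na - 1) * phi_a + (nb - 1) * phi_b) / (na + nb - 2)
    phi = np.maximum(phi, 1e-8)

    log2fc = np.log2((ma + 0.5) / (mb + 0.5))
    ln2 = math.log(2.0)
    var_la = (ma + phi * ma ** 2) / na / (ma + 0.5) ** 2
    var_lb = (mb + phi * mb ** 2) / nb / (mb + 0.5) ** 2
    se = np.sqrt(var_la + var_lb) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    allzero = (ma == 0) & (mb == 0)
    p[allzero] = 1.0
    log2fc[allzero] = 0.0
    p[~np.isfinite(p)] = 1.0
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"feature": norm.index, "log2fc": log2fc, "p": p,
                         "padj": padj, "mean_a": ma, "mean_b": mb}
                        ).set_index("feature")


def filter_differential(table: pd.DataFrame, padj_max: float = 0.05,
                        min_abs_lfc: float = 0.5) -> dict[str, list[str]]:
    """Split significant features by direction.

    Inclusive on ``padj <= padj_max``, strict on ``|log2fc| > min_abs_lfc``;
    returns ``{"a_up": [...], "b_up": [...]}``.
    """
    if not (np.isfinite(padj_max) and np.isfinite(min_abs_lfc)):
        raise ValueError("thresholds must be finite")
    sig = table[(table.padj <= padj_max) & (table.log2fc.abs() > min_abs_lfc)]
    return {"a_up": list(sig.index[sig.log2fc > 0]),
            "b_up": list(sig.index[sig.log2fc < 0])}
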