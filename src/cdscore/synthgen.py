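"""Synthetic cohorts with planted ground truth for every pipeline stage.

The study design emulated here is a three-subtype bladder-tumor cohort:
two urothelial chromatin states — luminal-like inflammatory (LLI) and
basal-like (BL) — plus the micropapillary (MP) histological variant.  The
generators plant known effects (differential H3K27ac peaks linked to
differential genes, copy-number segments with GC-dependent coverage bias,
vessel-proximal vs vessel-distal stain zones, subtype-dependent progression
hazards) so that every downstream estimator can be validated against the
truth it is supposed to recover.

All randomness flows from ``SimConfig.seed`` through named child streams,
so each generator is byte-reproducible independently of the others.

Model choices (none of which are estimates of any real cohort):

* counts are negative binomial with mean ``mu`` and variance
  ``mu + phi * mu**2`` (``phi`` the dispersion), the same parameterization
  the differential test assumes;
* the genome is three synthetic chromosomes of 200 Mb each, giving 600
  one-megabase bins, so each bin's k = 100 GC-matched background set is a
  modest fraction of the genome (as it is for a real genome) and planted
  copy-number segments contaminate it only mildly;
* per-bin GC fractions are drawn once from Beta(20, 20), a realistic
  spread around 0.5;
* stain colors are DAB brown (150, 90, 60), hematoxylin blue (70, 80, 160)
  and background (235, 230, 228) with Gaussian pixel noise, which makes the
  red-vs-blue pixel filter non-trivial;
* single-cell dropout is expression-dependent (probability
  ``dropout_rate * exp(-mu / median baseline)``), so highly induced marker
  genes are rarely lost, as in real droplet data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SUBTYPES = ("LLI", "BL", "MP")
CAF_TYPES = ("myCAF", "iCAF", "apCAF", "IFN-CAF", "PSCA-CAF")
MACRO_TYPES = ("M1", "M2")
CELL_TYPES = SUBTYPES + CAF_TYPES + MACRO_TYPES + ("other",)

# canonical single-gene markers used for CAF subtype assignment
CAF_MARKERS: dict[str, list[str]] = {
    "myCAF": ["FN1"],
    "iCAF": ["C3"],
    "apCAF": ["CD74"],
    "IFN-CAF": ["SLC14A1"],
    "PSCA-CAF": ["PSCA"],
}
M1_MARKERS = ["CD80", "CD86", "NOS2", "IL12B", "IL1B",
              "CXCL9", "CXCL10", "CXCL11", "EMP1"]
M2_MARKERS = ["CD163", "ARG1", "IL10", "TGFB1", "C1QA", "C1QB", "C1QC", "MMP9"]


class ConfigError(ValueError):
    """Raised when a SimConfig is internally inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study; defaults define the standard conditions.

    ``lib_size_range`` bounds the multiplicative library-depth factor per
    sample; ``gc_bias_coeffs`` are polynomial coefficients (low order first)
    mapping GC fraction to relative coverage; ``hazard_ratio`` is the
    LLI-vs-BL progression hazard ratio.
    """

    # bulk cohort
    n_samples_per_subtype: int = 6
    n_peaks: int = 2000
    n_genes: int = 1500
    n_diff_peaks_per_subtype: int = 15
    planted_lfc: float = 6.0
    nb_dispersion: float = 0.05
    lib_size_range: tuple[float, float] = (0.7, 1.3)
    base_mean: float = 50.0
    base_log_sd: float = 0.5
    # genome model: 600 one-megabase bins keep each bin's k=100 GC-matched
    # background a modest fraction of the genome, as in a real genome
    chrom_sizes: tuple[tuple[str, int], ...] = (
        ("chr1", 200_000_000), ("chr2", 200_000_000), ("chr3", 200_000_000))
    # single cells
    n_cells_per_type: int = 200
    dropout_rate: float = 0.3
    sc_depth: float = 5.0
    sc_marker_lfc: float = 6.0
    # scATAC fragments
    n_fragments: int = 1_000_000
    n_frag_cells: int = 200
    on_target_fraction: float = 0.3
    n_atac_peaks: int = 2000
    atac_peak_width: int = 1000
    cnv_segments: tuple[tuple[str, int, int, float], ...] = (
        ("chr1", 0, 30_000_000, 2.0),
        ("chr2", 0, 30_000_000, 0.5),
    )
    gc_bias_coeffs: tuple[float, ...] = (0.5, 1.0)
    bin_size: int = 1_000_000
    # IHC image
    image_size: int = 256
    vessel_geometry: Mapping[str, float] = field(
        default_factory=lambda: {"kind": "stripe", "width": 10})
    ihc_near_max: float = 40.0
    ihc_far_min: float = 120.0
    n_blobs: int = 12
    blob_radius: int = 6
    n_nuclei: int = 150
    nucleus_radius: int = 2
    noise_sigma: float = 8.0
    pixel_size: float = 1.0
    # spatial points
    n_points_per_category: int = 300
    attraction_radius: float = 50.0
    field_size: float = 1000.0
    n_anchor_clusters: int = 3
    anchor_cluster_sd: float = 30.0
    # survival
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.03
    censor_horizon: float = 72.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_samples_per_subtype, self.n_peaks, self.n_genes,
                  self.n_diff_peaks_per_subtype, self.n_cells_per_type,
                  self.n_fragments, self.image_size)
        if any(c <= 0 for c in counts):
            raise ConfigError("all counts must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ConfigError("dropout_rate must lie in [0, 1)")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise ConfigError("lib_size_range bounds must be positive and ordered")
        if self.hazard_ratio <= 0:
            raise ConfigError("hazard_ratio must be positive")
        sizes = dict(self.chrom_sizes)
        segs = sorted(self.cnv_segments)
        for chrom, start, end, ratio in segs:
            if ratio <= 0:
                raise ConfigError("copy_ratio must be positive")
            if chrom not in sizes or start < 0 or end > sizes[chrom] or start >= end:
                raise ConfigError(f"cnv segment outside {chrom} bounds")
        for (c1, s1, e1, _), (c2, s2, _, _) in zip(segs, segs[1:]):
            if c1 == c2 and s2 < e1:
                raise ConfigError("cnv_segments overlap")
        if 3 * self.n_diff_peaks_per_subtype > min(self.n_peaks, self.n_genes):
            raise ConfigError("more planted features than peaks/genes")


@dataclass
class GroundTruth:
    """Planted truth handed to tests; fields unused by a generator stay None."""

    subtype_of_sample: dict[str, str] | None = None
    diff_peak_ids: dict[str, list[str]] | None = None
    signature_genes: dict[str, list[str]] | None = None
    peak_to_gene: dict[str, str] | None = None
    cell_labels: pd.Series | None = None
    cnv_log2_of_bin: pd.Series | None = None
    marker_zone_masks: dict[str, np.ndarray] | None = None
    true_distances: dict[str, np.ndarray] | None = None


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Named child stream: independent generators keyed by (seed, label)."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean mu, var mu + phi mu^2); Poisson in the phi -> 0 limit."""
    mu = np.asarray(mu, dtype=float)
    if phi <= 0:
        return rng.poisson(mu)
    n = 1.0 / phi
    return rng.negative_binomial(n, n / (n + mu))


# ---------------------------------------------------------------------------
# bulk cohort


def simulate_bulk_cohort(cfg: SimConfig):
    """Peak and expression count matrices for a 3-subtype bulk cohort.

    Each planted differential peak sits within ~1 kb of the TSS of exactly
    one planted signature gene whose expression carries the same log2 fold
    change, so the peak-gene linkage stage can be validated end to end.

    Returns ``(peak_matrix, expr_matrix, gene_annotation, truth)`` where the
    matrices are DataFrames (features x samples), ``peak_matrix`` carries a
    ``peaks`` attribute with BED-style intervals, and ``gene_annotation`` has
    columns (gene_id, chrom, tss, strand).
    """
    rng = rng_for(cfg.seed, "bulk")
    n_per = cfg.n_samples_per_subtype
    if n_per < 2:
        raise ConfigError("need at least 2 samples per subtype")
    samples = [f"{st}_{i + 1}" for st in SUBTYPES for i in range(n_per)]
    subtype_of_sample = {s: s.rsplit("_", 1)[0] for s in samples}

    chroms = [c for c, _ in cfg.chrom_sizes]
    sizes = np.array([s for _, s in cfg.chrom_sizes], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    genome = int(offsets[-1])

    # gene annotation: TSS uniform over the genome
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    gpos = np.sort(rng.integers(0, genome, cfg.n_genes))
    gchrom_idx = np.searchsorted(offsets, gpos, side="right") - 1
    ann = pd.DataFrame({
        "gene_id": gene_ids,
        "chrom": [chroms[i] for i in gchrom_idx],
        "tss": gpos - offsets[gchrom_idx],
        "strand": rng.choice(["+", "-"], cfg.n_genes),
    })

    n_diff = cfg.n_diff_peaks_per_subtype
    planted_genes = rng.choice(cfg.n_genes, 3 * n_diff, replace=False)
    signature_genes = {st: sorted(gene_ids[g] for g in
                                  planted_genes[k * n_diff:(k + 1) * n_diff])
                       for k, st in enumerate(SUBTYPES)}

    # peaks: the first 3*n_diff are planted next to their signature gene TSS
    peak_ids = [f"peak_{i:05d}" for i in range(cfg.n_peaks)]
    mid = rng.integers(250, genome - 250, cfg.n_peaks)
    diff_peak_ids: dict[str, list[str]] = {st: [] for st in SUBTYPES}
    peak_to_gene: dict[str, str] = {}
    peak_subtype = np.full(cfg.n_peaks, "", dtype=object)
    idx = 0
    for k, st in enumerate(SUBTYPES):
        for g in planted_genes[k * n_diff:(k + 1) * n_diff]:
            jitter = int(rng.integers(-1000, 1001))
            mid[idx] = np.clip(int(offsets[gchrom_idx[g]]) + int(ann.tss[g]) + jitter,
                               250, genome - 250)
            diff_peak_ids[st].append(peak_ids[idx])
            peak_to_gene[peak_ids[idx]] = gene_ids[g]
            peak_subtype[idx] = st
            idx += 1
    pchrom_idx = np.searchsorted(offsets, mid, side="right") - 1
    peaks = pd.DataFrame({
        "chrom": [chroms[i] for i in pchrom_idx],
        "start": mid - offsets[pchrom_idx] - 250,
        "end": mid - offsets[pchrom_idx] + 250,
        "name": peak_ids,
    })

    lib = rng.uniform(*cfg.lib_size_range, len(samples))

    def _counts(n_feat: int, effect_of_feature: np.ndarray) -> np.ndarray:
        base = np.exp(rng.normal(np.log(cfg.base_mean), cfg.base_log_sd, n_feat))
        out = np.empty((n_feat, len(samples)), dtype=np.int64)
        for j, s in enumerate(samples):
            st = subtype_of_sample[s]
            lfc = np.where(effect_of_feature == st, cfg.planted_lfc, 0.0)
            mu = lib[j] * base * 2.0 ** lfc
            out[:, j] = _nb_sample(rng, mu, cfg.nb_dispersion)
        return out

    peak_counts = pd.DataFrame(_counts(cfg.n_peaks, peak_subtype),
                               index=peak_ids, columns=samples)
    gene_subtype = np.full(cfg.n_genes, "", dtype=object)
    for k, st in enumerate(SUBTYPES):
        gene_subtype[planted_genes[k * n_diff:(k + 1) * n_diff]] = st
    expr_counts = pd.DataFrame(_counts(cfg.n_genes, gene_subtype),
                               index=gene_ids, columns=samples)
    peak_counts.attrs["peaks"] = peaks

    truth = GroundTruth(subtype_of_sample=subtype_of_sample,
                        diff_peak_ids=diff_peak_ids,
                        signature_genes=signature_genes,
                        peak_to_gene=peak_to_gene)
    return peak_counts, expr_counts, ann, truth


# ---------------------------------------------------------------------------
# single cells


def simulate_single_cells(cfg: SimConfig,
                          signature_genes: Mapping[str, Sequence[str]] | None = None):
    """Gene-by-cell count matrix mixing tumor subtypes, CAFs and macrophages.

    Tumor cells of each subtype overexpress that subtype's signature genes by
    ``sc_marker_lfc`` log2 units; CAF and macrophage populations overexpress
    their canonical markers.  Dropout probability decays with expected
    expression, so induced markers are rarely zeroed.
    """
    rng = rng_for(cfg.seed, "cells")
    if signature_genes is None:
        signature_genes = {st: [f"g{st}{i:02d}" for i in range(15)]
                           for st in SUBTYPES}
    if any(len(v) == 0 for v in signature_genes.values()):
        raise ConfigError("empty signature gene set")

    marked: dict[str, list[str]] = {st: list(signature_genes[st]) for st in SUBTYPES}
    marked.update({ct: list(gs) for ct, gs in CAF_MARKERS.items()})
    marked["M1"] = list(M1_MARKERS)
    marked["M2"] = list(M2_MARKERS)
    marked["other"] = []

    special = [g for gs in marked.values() for g in gs]
    n_bg = max(cfg.n_genes - len(special), 200)
    genes = special + [f"BG{i:05d}" for i in range(n_bg)]

    base = np.exp(rng.normal(np.log(cfg.sc_depth), cfg.base_log_sd, len(genes)))
    gene_index = {g: i for i, g in enumerate(genes)}

    cells, labels, columns = [], [], []
    for ct in CELL_TYPES:
        mu = np.tile(base, (cfg.n_cells_per_type, 1))
        cols = [gene_index[g] for g in marked[ct]]
        mu[:, cols] *= 2.0 ** cfg.sc_marker_lfc
        counts = _nb_sample(rng, mu, cfg.nb_dispersion)
        if cfg.dropout_rate > 0:
            p_drop = cfg.dropout_rate * np.exp(-mu / np.median(base))
            counts = np.where(rng.random(mu.shape) < p_drop, 0, counts)
        cells.append(counts)
        labels += [ct] * cfg.n_cells_per_type
        columns += [f"{ct}_c{i:04d}" for i in range(cfg.n_cells_per_type)]

    matrix = pd.DataFrame(np.concatenate(cells).T, index=genes, columns=columns)
    truth = GroundTruth(cell_labels=pd.Series(labels, index=columns, name="cell_type"),
                        signature_genes={st: list(v) for st, v in signature_genes.items()})
    return matrix, truth


# ---------------------------------------------------------------------------
# scATAC fragments with planted CNV and GC bias


def gc_bias(coeffs: Sequence[float], gc: np.ndarray) -> np.ndarray:
    """Relative coverage as a polynomial in GC fraction (low order first)."""
    return np.polynomial.polynomial.polyval(np.asarray(gc, float), list(coeffs))


def simulate_fragments(cfg: SimConfig):
    """Fragment set whose off-target density tracks copy ratio x GC bias.

    Returns ``(fragments, bins, peaks, truth)``: fragments as a DataFrame
    (chrom, start, end, barcode), 1 Mb genome bins with fixed GC fractions,
    an accessibility peak set (on-target fragments are emitted inside it),
    and the per-bin true log2 copy ratio.
    """
    from .cnv_atac import make_bins  # shared binning logic

    rng = rng_for(cfg.seed, "fragments")
    bins = make_bins(dict(cfg.chrom_sizes), bin_size=cfg.bin_size,
                     gc_source=lambda chrom, start, end:
                     float(rng_for(cfg.seed, f"gc:{chrom}:{start}").beta(20, 20)))

    # non-overlapping accessibility peaks on a regular lattice, jittered
    sizes = dict(cfg.chrom_sizes)
    peak_rows = []
    per_chrom = cfg.n_atac_peaks // len(sizes)
    for chrom, size in cfg.chrom_sizes:
        slots = np.linspace(0, size - 2 * cfg.atac_peak_width, per_chrom).astype(np.int64)
        starts = slots + rng.integers(0, cfg.atac_peak_width // 2, per_chrom)
        for k, s in enumerate(starts):
            peak_rows.append((chrom, int(s), int(s) + cfg.atac_peak_width,
                              f"apeak_{chrom}_{k:05d}"))
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "name"])

    ratio = np.ones(len(bins.index))
    bin_df = bins.table
    for chrom, start, end, r in cfg.cnv_segments:
        mid = (bin_df.start + bin_df.end) // 2
        hit = (bin_df.chrom == chrom) & (mid >= start) & (mid < end)
        ratio[hit.to_numpy()] = r

    from .cnv_atac import _peak_overlap
    eff = (bin_df.end - bin_df.start).to_numpy() - _peak_overlap(bin_df, peaks)

    barcodes = np.array([f"BC{i:04d}" for i in range(cfg.n_frag_cells)])
    n_on = int(round(cfg.n_fragments * cfg.on_target_fraction))
    n_off = cfg.n_fragments - n_on

    # off-target: bin weighted by copy ratio x GC bias x effective length,
    # position uniform on the non-peak part of the bin (rejection sampling)
    w = ratio * gc_bias(cfg.gc_bias_coeffs, bins.gc) * eff
    w = np.clip(w, 0, None)
    bin_choice = rng.choice(len(bin_df), n_off, p=w / w.sum())
    starts = bin_df.start.to_numpy()[bin_choice]
    ends = bin_df.end.to_numpy()[bin_choice]
    pos = rng.integers(starts, ends)
    chrom_of = bin_df.chrom.to_numpy()[bin_choice]
    p_by_chrom = {c: peaks[peaks.chrom == c].sort_values("start") for c in sizes}
    for _ in range(50):  # reject midpoints falling inside peaks
        bad = np.zeros(n_off, dtype=bool)
        for c, p in p_by_chrom.items():
            m = chrom_of == c
            j = np.searchsorted(p.start.to_numpy(), pos[m], side="right") - 1
            inside = (j >= 0) & (pos[m] < p.end.to_numpy()[np.clip(j, 0, None)])
            bad[np.flatnonzero(m)[inside]] = True
        if not bad.any():
            break
        pos[bad] = rng.integers(starts[bad], ends[bad])

    # on-target: fragments centered inside peaks, also scaled by copy ratio
    peak_bin = np.empty(len(peaks), dtype=np.int64)
    for c in sizes:
        m = (peaks.chrom == c).to_numpy()
        b = bin_df[bin_df.chrom == c]
        pm = ((peaks.start + peaks.end) // 2).to_numpy()[m]
        peak_bin[m] = b.index.to_numpy()[
            np.searchsorted(b.start.to_numpy(), pm, side="right") - 1]
    pw = ratio[peak_bin]
    peak_choice = rng.choice(len(peaks), n_on, p=pw / pw.sum())
    on_pos = rng.integers(peaks.start.to_numpy()[peak_choice] + 10,
                          peaks.end.to_numpy()[peak_choice] - 10)

    all_chrom = np.concatenate([chrom_of, peaks.chrom.to_numpy()[peak_choice]])
    all_mid = np.concatenate([pos, on_pos])
    length = rng.integers(100, 301, cfg.n_fragments)
    frag_start = np.maximum(all_mid - length // 2, 0)
    frag_end = frag_start + length
    frags = pd.DataFrame({
        "chrom": all_chrom,
        "start": frag_start,
        "end": frag_end,
        "barcode": rng.choice(barcodes, cfg.n_fragments),
    }).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    cnv_log2 = pd.Series(np.log2(ratio), index=bins.index, name="true_log2")
    truth = GroundTruth(cnv_log2_of_bin=cnv_log2)
    return frags, bins, peaks, truth


# ---------------------------------------------------------------------------
# IHC image

DAB = np.array([150, 90, 60], dtype=float)
HEMATOXYLIN = np.array([70, 80, 160], dtype=float)
BACKGROUND = np.array([235, 230, 228], dtype=float)


def _disk(mask: np.ndarray, cy: int, cx: int, r: int) -> None:
    h, w = mask.shape
    y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
    x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
    yy, xx = np.ogrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def simulate_ihc_image(cfg: SimConfig, swap_zones: bool = False):
    """Dual-marker stained RGB image with a vessel mask and known geometry.

    The "near" marker's DAB blobs sit within ``ihc_near_max`` pixels of the
    vessel stripe; the "far" marker's blobs start beyond ``ihc_far_min``.
    ``swap_zones`` exchanges the two zones (symmetry checks).  Returns
    ``(rgb, vessel_mask, truth)``.
    """
    from scipy.ndimage import distance_transform_edt

    if cfg.image_size < 64:
        raise ConfigError("image_size must be at least 64")
    rng = rng_for(cfg.seed, "ihc")
    S = cfg.image_size
    vessel = np.zeros((S, S), dtype=bool)
    geom = dict(cfg.vessel_geometry)
    if geom.get("kind", "stripe") == "stripe":
        vessel[:, :int(geom.get("width", 10))] = True
    else:
        raise ConfigError(f"unknown vessel geometry {geom!r}")
    if not vessel.any():
        raise ConfigError("vessel mask is empty")

    dist = distance_transform_edt(~vessel)
    zones = {"near": (1.0, cfg.ihc_near_max),
             "far": (cfg.ihc_far_min, np.inf)}
    markers = ("KRT5", "KRT20")
    if swap_zones:
        markers = markers[::-1]
    masks: dict[str, np.ndarray] = {}
    for marker, (lo, hi) in zip(markers, (zones["near"], zones["far"])):
        m = np.zeros((S, S), dtype=bool)
        ok = np.argwhere((dist >= float(lo)) & (dist <= hi) & ~vessel)
        if len(ok) == 0:
            raise ConfigError("no room for marker zone; enlarge image")
        for cy, cx in ok[rng.choice(len(ok), cfg.n_blobs, replace=False)]:
            _disk(m, cy, cx, cfg.blob_radius)
        m &= ~vessel
        masks[marker] = m

    rgb = np.tile(BACKGROUND, (S, S, 1))
    nuclei = np.zeros((S, S), dtype=bool)
    if cfg.n_nuclei > 0:
        cy = rng.integers(0, S, cfg.n_nuclei)
        cx = rng.integers(0, S, cfg.n_nuclei)
        for y, x in zip(cy, cx):
            _disk(nuclei, y, x, cfg.nucleus_radius)
    rgb[nuclei] = HEMATOXYLIN
    for marker in markers:  # DAB painted last: marker signal dominates nuclei
        rgb[masks[marker]] = DAB
    if cfg.noise_sigma > 0:
        rgb = rgb + rng.normal(0, cfg.noise_sigma, rgb.shape)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        marker_zone_masks=masks,
        true_distances={m: dist[masks[m]] * cfg.pixel_size for m in masks})
    return rgb, vessel, truth


# ---------------------------------------------------------------------------
# spatial points


def simulate_spatial(cfg: SimConfig, anchor_cat: str = "MP",
                     target_cat: str = "myCAF",
                     other_cats: Sequence[str] = ("iCAF", "apCAF", "other"),
                     uniform: bool = False) -> pd.DataFrame:
    """Point pattern where the target category clusters around anchors.

    Anchor cells sit in a few tight clumps (tumor nests: Gaussian clusters
    of sd ``anchor_cluster_sd`` around uniform centers); target points are
    placed within ``attraction_radius`` of randomly chosen anchors (unless
    ``uniform``); the "other" categories are uniform on the square.
    Returns a table (x, y, label).
    """
    rng = rng_for(cfg.seed, "spatial")
    n = cfg.n_points_per_category
    L = cfg.field_size
    rows = []

    centers = rng.uniform(0.2 * L, 0.8 * L, (cfg.n_anchor_clusters, 2))
    which = rng.integers(0, cfg.n_anchor_clusters, n)
    ax = np.clip(centers[which, 0] + rng.normal(0, cfg.anchor_cluster_sd, n), 0, L)
    ay = np.clip(centers[which, 1] + rng.normal(0, cfg.anchor_cluster_sd, n), 0, L)
    rows.append(pd.DataFrame({"x": ax, "y": ay, "label": anchor_cat}))

    if uniform:
        tx, ty = rng.uniform(0, L, n), rng.uniform(0, L, n)
    else:
        host = rng.integers(0, n, n)
        r = cfg.attraction_radius * np.sqrt(rng.random(n))
        theta = rng.uniform(0, 2 * np.pi, n)
        tx = np.clip(ax[host] + r * np.cos(theta), 0, L)
        ty = np.clip(ay[host] + r * np.sin(theta), 0, L)
    rows.append(pd.DataFrame({"x": tx, "y": ty, "label": target_cat}))

    for cat in other_cats:
        rows.append(pd.DataFrame({"x": rng.uniform(0, L, n),
                                  "y": rng.uniform(0, L, n), "label": cat}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# survival


def simulate_survival(labels: Mapping[str, str], cfg: SimConfig) -> pd.DataFrame:
    """Exponential progression times with class-dependent hazard.

    Classes containing "LLI" carry ``hazard_ratio`` times the baseline (BL)
    hazard; censoring is independent uniform on (0, censor_horizon].
    Returns (unit_id, time, event, group).
    """
    rng = rng_for(cfg.seed, "survival")
    units = list(labels)
    hazards = []
    for u in units:
        lab = labels[u]
        if "LLI" in lab:
            hazards.append(cfg.baseline_hazard * cfg.hazard_ratio)
        elif "BL" in lab or "MP" in lab or "intermediate" in lab:
            hazards.append(cfg.baseline_hazard)
        else:
            raise ValueError(f"unknown class label {lab!r} for unit {u!r}")
    t_event = rng.exponential(1.0 / np.asarray(hazards))
    t_cens = rng.uniform(0, cfg.censor_horizon, len(units))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"unit_id": units, "time": time, "event": event,
                         "group": [labels[u] for u in units]})
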