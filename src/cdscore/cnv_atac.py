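"""Copy-number inference from scATAC off-target fragments.

Sparse single-cell ATAC libraries carry most of their information inside
accessibility peaks, but the fragments *outside* peaks sample the genome
roughly uniformly and therefore track DNA copy number.  The caller tiles
the genome into large (1 Mb) bins, counts off-target fragments per bin,
normalizes by the bin's *effective window* (bin length minus peak-covered
length), and compares each bin against the mean coverage of its k = 100
closest bins in GC fraction.  The GC-matched background absorbs the
amplification bias that makes raw coverage correlate with GC content, so
the resulting log2 fold change reflects copy ratio rather than chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases in a sequence (case-insensitive)."""
    s = seq.upper()
    if not s:
        return float("nan")
    return (s.count("G") + s.count("C")) / len(s)


@dataclass
class GenomeBins:
    """Half-open tiling bins with per-bin GC fraction and effective length."""

    table: pd.DataFrame          # columns: chrom, start, end; RangeIndex
    gc: np.ndarray               # GC fraction per bin, NaN when unknown
    effective_length: np.ndarray  # bp per bin after peak subtraction
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = ~np.isfinite(self.gc)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def index(self) -> pd.Index:
        t = self.table
        return pd.Index([f"{c}:{s}-{e}" for c, s, e in
                         zip(t.chrom, t.start, t.end)], name="bin")


def _read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name, chunks = None, []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name, chunks = line[1:].split()[0], []
        else:
            chunks.append(line.strip())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def make_bins(chrom_sizes: Mapping[str, int], bin_size: int = 1_000_000,
              gc_source: str | Path | Mapping | Callable | None = None,
              peaks: pd.DataFrame | None = None) -> GenomeBins:
    """Tile chromosomes into half-open bins and annotate GC per bin.

    ``gc_source`` may be a FASTA path (GC computed by windowing the
    sequence), a mapping ``(chrom, start) -> gc``, or a callable
    ``(chrom, start, end) -> gc``.  Bins without a GC value are masked.
    Terminal partial bins keep their true length.  When ``peaks`` is given,
    ``effective_length`` is reduced by the peak overlap in each bin.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, bin_size, dtype=np.int64)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + bin_size, size))))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    gc = np.full(len(table), np.nan)
    if gc_source is not None:
        if isinstance(gc_source, (str, Path)):
            seqs = _read_fasta(gc_source)
            for i, row in table.iterrows():
                seq = seqs.get(row.chrom, "")
                gc[i] = gc_fraction(seq[row.start:row.end])
        elif callable(gc_source):
            gc[:] = [gc_source(r.chrom, r.start, r.end) for r in table.itertuples()]
        else:
            for i, row in table.iterrows():
                gc[i] = gc_source.get((row.chrom, row.start), np.nan)

    eff = (table.end - table.start).to_numpy(dtype=float)
    if peaks is not None:
        eff = eff - _peak_overlap(table, peaks)
    return GenomeBins(table=table, gc=gc, effective_length=eff)


def _peak_overlap(table: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    overlap = np.zeros(len(table))
    for chrom, p in peaks.groupby("chrom"):
        sel = table.chrom == chrom
        for i in np.flatnonzero(sel.to_numpy()):
            s, e = table.start.iat[i], table.end.iat[i]
            o = np.minimum(p.end.to_numpy(), e) - np.maximum(p.start.to_numpy(), s)
            overlap[i] = o[o > 0].sum()
    return overlap


def _assign_bins(chrom: np.ndarray, pos: np.ndarray,
                 table: pd.DataFrame) -> np.ndarray:
    """Bin index containing each position (half-open); -1 when outside."""
    out = np.full(len(pos), -1, dtype=np.int64)
    for c, b in table.groupby("chrom", sort=False):
        m = chrom == c
        if not m.any():
            continue
        j = np.searchsorted(b.start.to_numpy(), pos[m], side="right") - 1
        valid = (j >= 0) & (pos[m] < b.end.to_numpy()[np.clip(j, 0, None)])
        idx = np.flatnonzero(m)
        out[idx[valid]] = b.index.to_numpy()[j[valid]]
    return out


def _in_intervals(chrom: np.ndarray, pos: np.ndarray,
                  intervals: pd.DataFrame) -> np.ndarray:
    """Membership of positions in a set of non-overlapping intervals."""
    hit = np.zeros(len(pos), dtype=bool)
    for c, p in intervals.groupby("chrom"):
        m = chrom == c
        if not m.any():
            continue
        starts = np.sort(p.start.to_numpy())
        ends = p.sort_values("start").end.to_numpy()
        j = np.searchsorted(starts, pos[m], side="right") - 1
        inside = (j >= 0) & (pos[m] < ends[np.clip(j, 0, None)])
        hit[np.flatnonzero(m)[inside]] = True
    return hit


def offtarget_coverage(frags: pd.DataFrame, bins: GenomeBins,
                       peaks: pd.DataFrame, unit: str = "pseudobulk",
                       cluster_of: Mapping[str, str] | None = None,
                       min_effective_frac: float = 0.10) -> pd.DataFrame:
    """Off-target fragment density per bin (fragments / effective kb).

    Fragments whose midpoint falls inside any peak are discarded; the rest
    are assigned to the bin containing their midpoint (half-open, so a
    midpoint on a boundary belongs to the right-hand bin).  Bins whose
    effective window is below ``min_effective_frac`` of the bin length are
    masked (NaN).  ``unit`` is ``"pseudobulk"``, ``"barcode"``, or
    ``"cluster"`` (requires ``cluster_of``).
    """
    table = bins.table
    bin_len = (table.end - table.start).to_numpy(dtype=float)
    if peaks is not None and len(peaks):
        eff = bin_len - _peak_overlap(table, peaks)
    else:
        eff = bins.effective_length

    chrom = frags.chrom.to_numpy()
    mid = ((frags.start.to_numpy() + frags.end.to_numpy()) // 2).astype(np.int64)
    off = ~_in_intervals(chrom, mid, peaks) if len(peaks) else np.ones(len(frags), bool)
    bin_idx = _assign_bins(chrom[off], mid[off], table)
    keep = bin_idx >= 0

    if unit == "pseudobulk":
        groups = pd.Series("pseudobulk", index=np.arange(keep.sum()))
    elif unit == "barcode":
        groups = pd.Series(frags.barcode.to_numpy()[off][keep])
    elif unit == "cluster":
        if cluster_of is None:
            raise ValueError("unit='cluster' requires a barcode->cluster map")
        groups = pd.Series(frags.barcode.to_numpy()[off][keep]).map(dict(cluster_of))
    else:
        raise ValueError(f"unknown unit {unit!r}")

    if unit == "pseudobulk":
        expected_units = ["pseudobulk"]
    elif unit == "barcode":
        expected_units = sorted(frags.barcode.unique())
    else:
        expected_units = sorted(set(dict(cluster_of).values()))
    counts = (pd.DataFrame({"bin": bin_idx[keep], "g": groups.to_numpy()})
              .groupby(["bin", "g"]).size().unstack(fill_value=0)
              .reindex(index=range(len(table)), columns=expected_units,
                       fill_value=0))
    dens = counts.to_numpy(dtype=float) / (eff[:, None] / 1000.0)
    masked = bins.mask | (eff < min_effective_frac * bin_len)
    dens[masked] = np.nan
    out = pd.DataFrame(dens, index=bins.index, columns=counts.columns.astype(str))
    out.columns.name = "unit"
    return out


def gc_matched_background(cov: pd.DataFrame, bins: GenomeBins,
                          k: int = 100) -> pd.DataFrame:
    """Per-bin background: mean density of the k closest unmasked bins in GC.

    The focal bin is excluded from its own background; ties in |delta GC|
    break by genomic order.  Raises when fewer than k+1 unmasked bins exist.
    """
    dens = cov.to_numpy(dtype=float)
    unmasked = np.flatnonzero(np.isfinite(dens).all(axis=1) & np.isfinite(bins.gc))
    if len(unmasked) < k + 1:
        raise ValueError(f"need at least {k + 1} unmasked bins, have {len(unmasked)}")
    gc = bins.gc
    bg = np.full_like(dens, np.nan)
    for b in range(len(bins)):
        if not np.isfinite(dens[b]).all() or not np.isfinite(gc[b]):
            continue
        cand = unmasked[unmasked != b]
        order = np.lexsort((cand, np.abs(gc[cand] - gc[b])))
        chosen = cand[order[:k]]
        bg[b] = dens[chosen].mean(axis=0)
    return pd.DataFrame(bg, index=cov.index, columns=cov.columns)


def cnv_fold_change(cov: pd.DataFrame, background: pd.DataFrame,
                    eps: float = 1e-3) -> pd.DataFrame:
    """log2((density + eps) / (background + eps)) per bin per unit.

    ``eps`` defaults to one fragment per effective megabase (0.001
    fragments/kb), keeping the ratio finite for sparse per-cell coverage.
    Masked bins propagate as NaN.
    """
    if not cov.index.equals(background.index) or not cov.columns.equals(background.columns):
        raise ValueError("coverage and background are not aligned")
    return np.log2((cov + eps) / (background + eps))


def call_cnv(frags: pd.DataFrame, bins: GenomeBins, peaks: pd.DataFrame,
             unit: str = "pseudobulk", k: int = 100, eps: float = 1e-3,
             cluster_of: Mapping[str, str] | None = None,
             exclude_chroms: tuple[str, ...] = ()) -> pd.DataFrame:
    """Full caller: coverage -> GC-matched background -> log2 fold change."""
    if exclude_chroms:
        keep = ~bins.table.chrom.isin(exclude_chroms).to_numpy()
        bins = GenomeBins(table=bins.table[keep].reset_index(drop=True),
                          gc=bins.gc[keep],
                          effective_length=bins.effective_length[keep],
                          mask=bins.mask[keep])
    cov = offtarget_coverage(frags, bins, peaks, unit=unit, cluster_of=cluster_of)
    bg = gc_matched_background(cov, bins, k=k)
    return cnv_fold_change(cov, bg, eps=eps)
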