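"""Readers and writers for the plain-text formats used across the pipeline.

Peaks travel as BED (0-based, half-open), count matrices as TSV or
MatrixMarket, gene sets as GMT, scATAC fragments as a 10x-style
``fragments.tsv`` (chrom, start, end, barcode, count), images as 8-bit RGB
PNG, and everything tabular as TSV.  Every writer has a matching reader and
the pair round-trips losslessly.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import io as spio
from scipy import sparse

BED_COLUMNS = ["chrom", "start", "end", "name"]
FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write intervals (chrom, start, end, name) as a 0-based half-open BED."""
    intervals[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)
    return df.astype({"start": np.int64, "end": np.int64})


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    """Feature-by-sample count matrix as TSV, feature ids in the first column."""
    counts.to_csv(path, sep="\t", index_label="feature")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature")


def write_counts_mtx(counts: pd.DataFrame, prefix: str | Path) -> None:
    """MatrixMarket triple: ``<prefix>.mtx`` plus row/column label sidecars."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(counts.to_numpy()))
    prefix.with_suffix(".rows.txt").write_text("\n".join(map(str, counts.index)) + "\n")
    prefix.with_suffix(".cols.txt").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_counts_mtx(prefix: str | Path) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx"))).toarray()
    rows = prefix.with_suffix(".rows.txt").read_text().splitlines()
    cols = prefix.with_suffix(".cols.txt").read_text().splitlines()
    return pd.DataFrame(mat, index=rows, columns=cols)


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    lines = []
    for name, genes in gene_sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *map(str, genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        sets[fields[0]] = fields[2:]
    return sets


def write_fragments(fragments: pd.DataFrame, path: str | Path) -> None:
    """10x-layout fragment file, sorted by chrom then start; ``.gz`` suffix gzips."""
    df = fragments.copy()
    if "count" not in df.columns:
        df["count"] = 1
    df = df.sort_values(["chrom", "start"], kind="mergesort")
    path = Path(path)
    text = df[FRAGMENT_COLUMNS].to_csv(sep="\t", header=False, index=False)
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        path.write_text(text)


def read_fragments(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        df = pd.read_csv(fh, sep="\t", header=None, names=FRAGMENT_COLUMNS)
    return df.astype({"start": np.int64, "end": np.int64, "count": np.int64})


def write_image_png(rgb: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(rgb, dtype=np.uint8), mode="RGB").save(path)


def read_image_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray((np.asarray(mask, bool) * np.uint8(255)), mode="L").save(path)


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
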