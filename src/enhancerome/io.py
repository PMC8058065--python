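"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: chrom.sizes, BED3/4/6, narrowPeak (10-column,
column 10 = summit offset, -1 = absent), genes TSV, count-matrix TSV,
BEDPE-style interaction pairs with a gene column, dense matrix TSV, and
MatrixMarket cell x gene matrices with sidecar barcode/gene/label tables.
BED-derived coordinates are 0-based half-open on disk and in memory.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .intervals import GenomeLayout, GenomicInterval, IntervalSet


# ---------------------------------------------------------------- chrom.sizes

def read_chrom_sizes(path: str | os.PathLike) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeLayout(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))


def write_chrom_sizes(genome: GenomeLayout, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.chromosomes.items():
            fh.write(f"{chrom}\t{length}\n")


# ------------------------------------------------------------------- BED

def read_bed(path: str | os.PathLike) -> IntervalSet:
    """Read BED3/4/6; column 4 -> name, column 5 -> score."""
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            ivs.append(
                GenomicInterval(
                    f[0],
                    int(f[1]),
                    int(f[2]),
                    name=f[3] if len(f) > 3 else None,
                    score=float(f[4]) if len(f) > 4 and f[4] != "." else None,
                )
            )
    return IntervalSet(ivs)


def write_bed(regions: IntervalSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in regions:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(repr(iv.score))
            fh.write("\t".join(fields) + "\n")


# ------------------------------------------------------------ segmentations

def read_segmentation_bed(path: str | os.PathLike) -> IntervalSet:
    """4-column BED: chrom, start, end, state label (label -> name)."""
    return read_bed(path)


def write_segmentation_bed(segments: IntervalSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in segments:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


# -------------------------------------------------------------- narrowPeak

def read_narrowpeak(path: str | os.PathLike) -> IntervalSet:
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            summit = int(f[9])
            ivs.append(
                GenomicInterval(
                    f[0],
                    int(f[1]),
                    int(f[2]),
                    name=f[3] if f[3] != "." else None,
                    score=float(f[6]),  # signalValue carries the score
                    summit=summit if summit >= 0 else None,
                )
            )
    return IntervalSet(ivs)


def write_narrowpeak(peaks: IntervalSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            score = iv.score if iv.score is not None else 0.0
            summit = iv.summit if iv.summit is not None else -1
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name or ".",
                        "0",
                        ".",
                        repr(score),
                        "-1",
                        "-1",
                        str(summit),
                    ]
                )
                + "\n"
            )


# ------------------------------------------------------------------ genes

GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "biotype"]


def read_genes_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"genes TSV missing columns: {sorted(missing)}")
    return df


def write_genes_tsv(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ count matrix

def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Region x sample integer counts; index = 'chrom:start-end' strings."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df


def write_counts_tsv(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="region")


def read_groups_tsv(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample"], df["group"]))


def write_groups_tsv(groups: dict[str, str], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"sample": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ interactions

def read_interactions(path: str | os.PathLike) -> pd.DataFrame:
    """BEDPE-style pairs: enhancer-side anchor + linked gene_id column."""
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "gene_id": str},
    )


def write_interactions(pairs: pd.DataFrame, path: str | os.PathLike) -> None:
    pairs[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )


# ------------------------------------------------------------- dense matrix

def read_matrix_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df


def write_matrix_tsv(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    matrix.to_csv(path, sep="\t", index_label="id")


# ----------------------------------------------------------------- MTX trio

def read_cell_matrix(directory: str | os.PathLike) -> tuple[pd.DataFrame, pd.Series]:
    """Read matrix.mtx + barcodes.tsv + genes.tsv + labels.tsv.

    Returns a dense cells x genes DataFrame and a per-cell label Series.
    """
    directory = Path(directory)
    mat = scipy.io.mmread(directory / "matrix.mtx")
    barcodes = pd.read_csv(directory / "barcodes.tsv", header=None)[0].astype(str)
    genes = pd.read_csv(directory / "genes.tsv", header=None)[0].astype(str)
    labels = pd.read_csv(directory / "labels.tsv", sep="\t", dtype=str)
    dense = pd.DataFrame(
        np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat),
        index=barcodes.to_numpy(),
        columns=genes.to_numpy(),
    )
    label_series = labels.set_index("barcode")["label"].reindex(barcodes)
    return dense, label_series


def write_cell_matrix(
    matrix: pd.DataFrame, labels: pd.Series, directory: str | os.PathLike
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(matrix.to_numpy())
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sparse)
    matrix.index.to_series().to_csv(
        directory / "barcodes.tsv", index=False, header=False
    )
    pd.Series(matrix.columns).to_csv(directory / "genes.tsv", index=False, header=False)
    pd.DataFrame({"barcode": matrix.index, "label": labels.loc[matrix.index]}).to_csv(
        directory / "labels.tsv", sep="\t", index=False
    )
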