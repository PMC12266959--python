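"""Reading and writing expression matrices, labels, and homolog tables.

On-disk matrices follow the 10x convention (genes x cells, Matrix Market
COO plus genes.tsv / barcodes.tsv companions) or a dense TSV with gene
columns; in memory everything is cells x genes. Orientation is always
explicit at the call site.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import ExpressionDataset

MTX_NAME = "matrix.mtx"
GENES_NAME = "genes.tsv"
BARCODES_NAME = "barcodes.tsv"
LABELS_NAME = "labels.tsv"
DENSE_NAME = "matrix.tsv"


def write_dataset(ds: ExpressionDataset, out_dir, fmt: str = "mtx") -> Path:
    """Write a dataset to `out_dir` as MTX triplet or dense TSV; returns dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        mat = scipy.sparse.coo_matrix(ds.matrix.T)  # genes x cells on disk
        scipy.io.mmwrite(str(out_dir / MTX_NAME), mat)
        pd.Series(ds.gene_names).to_csv(
            out_dir / GENES_NAME, sep="\t", header=False, index=False
        )
        pd.Series(ds.cell_ids).to_csv(
            out_dir / BARCODES_NAME, sep="\t", header=False, index=False
        )
    elif fmt == "tsv":
        df = pd.DataFrame(ds.matrix.T, index=ds.gene_names, columns=ds.cell_ids)
        df.to_csv(out_dir / DENSE_NAME, sep="\t")
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'mtx' or 'tsv')")
    if ds.labels is not None:
        pd.DataFrame({"cell_id": ds.cell_ids, "cell_type": ds.labels}).to_csv(
            out_dir / LABELS_NAME, sep="\t", header=False, index=False
        )
    return out_dir


def read_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns (cell id, type)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_dataset(
    path,
    orientation: str = "genes-by-cells",
    labels_path=None,
    domain: str = "source",
    layer: str = "counts",
) -> ExpressionDataset:
    """Read an MTX triplet directory or a dense delimited file.

    `orientation` declares the on-disk layout; the returned matrix is always
    cells x genes. If a labels file is given (or labels.tsv sits next to an
    MTX triplet), labels are joined on cell id; ids in the label file that do
    not match any barcode raise an error naming them.
    """
    if orientation not in ("genes-by-cells", "cells-by-genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if path.is_dir():
        mtx = path / MTX_NAME
        dense = path / DENSE_NAME
        if mtx.exists():
            matrix = np.asarray(scipy.io.mmread(str(mtx)).todense())
            genes = pd.read_csv(path / GENES_NAME, sep="\t", header=None, dtype=str)
            gene_names = list(genes.iloc[:, 0])
            barcodes = pd.read_csv(
                path / BARCODES_NAME, sep="\t", header=None, dtype=str
            )
            cell_ids = list(barcodes.iloc[:, 0])
        elif dense.exists():
            if labels_path is None and (path / LABELS_NAME).exists():
                labels_path = path / LABELS_NAME
            return read_dataset(
                dense, orientation=orientation, labels_path=labels_path,
                domain=domain, layer=layer,
            )
        else:
            raise FileNotFoundError(f"no {MTX_NAME} or {DENSE_NAME} in {path}")
        if labels_path is None and (path / LABELS_NAME).exists():
            labels_path = path / LABELS_NAME
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        matrix = df.to_numpy()
        gene_names = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]

    if orientation == "genes-by-cells":
        matrix = matrix.T
    else:
        gene_names, cell_ids = cell_ids, gene_names

    if len(gene_names) != len(set(gene_names)):
        dupes = sorted({g for g in gene_names if gene_names.count(g) > 1})
        raise ValueError(
            f"duplicate gene names (caller must deduplicate): {dupes[:5]}"
        )

    labels = None
    if labels_path is not None:
        mapping = read_labels(labels_path)
        missing = [c for c in mapping if c not in set(cell_ids)]
        if missing:
            raise ValueError(
                f"label file contains ids absent from barcodes: {missing[:10]}"
            )
        unlabeled = [c for c in cell_ids if c not in mapping]
        if unlabeled:
            raise ValueError(
                f"cells missing from label file: {unlabeled[:10]}"
            )
        labels = [mapping[c] for c in cell_ids]

    return ExpressionDataset(
        matrix=matrix,
        gene_names=gene_names,
        cell_ids=cell_ids,
        domain=domain,
        layer=layer,
        labels=labels,
    )


def read_homolog_table(path, header: bool = False) -> list[tuple[str, str]]:
    """Two-column TSV mapping species-A gene names to species-B gene names."""
    df = pd.read_csv(path, sep="\t", header=0 if header else None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"homolog table {path} needs two columns")
    return list(zip(df.iloc[:, 0], df.iloc[:, 1]))
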