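"""In-memory container for a single-domain expression matrix."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

LAYERS = ("counts", "tpm", "lognorm", "hvg")
DOMAINS = ("source", "target")


@dataclass
class ExpressionDataset:
    """A cells x genes expression matrix with identifiers and optional labels.

    `layer` records what the values are (raw counts, TPM, log-normalised, or
    log-normalised restricted to HVGs); `domain` tags whether the cells come
    from the labelled reference or the unlabelled query dataset.
    """

    matrix: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    domain: str = "source"
    layer: str = "counts"
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.domain not in DOMAINS:
            raise ValueError(f"domain must be one of {DOMAINS}, got {self.domain!r}")
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        n_cells, n_genes = self.matrix.shape
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_names):
            raise ValueError(
                f"matrix has {n_genes} columns but {len(self.gene_names)} gene names"
            )
        if len(set(self.gene_names)) != n_genes:
            raise ValueError("gene names must be unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell ids must be unique")
        if self.labels is not None:
            self.labels = [str(l) for l in self.labels]
            if len(self.labels) != n_cells:
                raise ValueError(
                    f"{len(self.labels)} labels for {n_cells} cells"
                )
        if np.any(self.matrix < 0):
            raise ValueError("expression values must be non-negative")
        if self.layer == "counts" and not np.allclose(
            self.matrix, np.round(self.matrix)
        ):
            raise ValueError("counts layer must contain integers")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def with_matrix(self, matrix: np.ndarray, layer: str) -> "ExpressionDataset":
        return replace(self, matrix=matrix, layer=layer)

    def subset_genes(self, idx: Sequence[int], layer: str | None = None) -> "ExpressionDataset":
        idx = np.asarray(idx, dtype=np.intp)
        return replace(
            self,
            matrix=self.matrix[:, idx],
            gene_names=[self.gene_names[i] for i in idx],
            layer=self.layer if layer is None else layer,
        )

    def to_anndata(self):
        """Export as an AnnData object (labels in obs['cell_type'])."""
        import anndata
        import pandas as pd

        obs = pd.DataFrame(index=self.cell_ids)
        obs["domain"] = self.domain
        if self.labels is not None:
            obs["cell_type"] = self.labels
        return anndata.AnnData(
            X=self.matrix.copy(),
            obs=obs,
            var=pd.DataFrame(index=self.gene_names),
            uns={"layer": self.layer},
        )
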