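"""Normalisation, HVG selection and cross-species gene mapping.

The pipeline mirrors standard scRNA-seq practice: depth normalisation (TPM
when gene lengths are known, CPM otherwise, or the ln(1 + scaled) Seurat
style log-normalisation), then ranking genes by vst-style standardised
variance and keeping the top `n_hvg` as network input features. Cross-species
transfer first maps gene names through a homolog table and restricts both
datasets to the shared, aligned gene set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionDataset


@dataclass
class PreprocessConfig:
    scale_factor: float = 10_000.0
    n_hvg: int = 2_000
    normalization: str = "lognorm"  # "tpm" or "lognorm"
    hvg_reference: str = "source"  # "source" or "concatenated"

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")
        if self.n_hvg <= 0:
            raise ValueError("n_hvg must be > 0")
        if self.normalization not in ("tpm", "lognorm"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.hvg_reference not in ("source", "concatenated"):
            raise ValueError(f"unknown hvg_reference {self.hvg_reference!r}")


def _check_counts(ds: ExpressionDataset, op: str) -> np.ndarray:
    if ds.layer != "counts":
        raise ValueError(f"{op} expects the counts layer, got {ds.layer!r}")
    totals = ds.matrix.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        ids = [ds.cell_ids[i] for i in zero[:10]]
        raise ValueError(f"cells with zero total counts (filter first): {ids}")
    return totals


def tpm_normalize(
    ds: ExpressionDataset, gene_lengths: np.ndarray | None = None
) -> ExpressionDataset:
    """Transcripts-per-million: length-corrected rates rescaled to 1e6 per cell.

    With no gene lengths (e.g. simulated data, UMI counts) lengths default to
    one and the result is counts-per-million.
    """
    _check_counts(ds, "tpm_normalize")
    counts = ds.matrix.astype(np.float64)
    if gene_lengths is not None:
        gene_lengths = np.asarray(gene_lengths, dtype=np.float64)
        if gene_lengths.shape != (ds.n_genes,):
            raise ValueError("gene_lengths must have one entry per gene")
        if np.any(gene_lengths <= 0):
            raise ValueError("gene lengths must be positive")
        counts = counts / gene_lengths[None, :]
    tpm = counts / counts.sum(axis=1, keepdims=True) * 1e6
    return ds.with_matrix(tpm, "tpm")


def lognorm(
    ds: ExpressionDataset, cfg: PreprocessConfig | None = None
) -> ExpressionDataset:
    """Seurat-style log-normalisation: ln(1 + count / cell_total * scale)."""
    cfg = cfg or PreprocessConfig()
    totals = _check_counts(ds, "lognorm")
    values = np.log1p(
        ds.matrix / totals[:, None].astype(np.float64) * cfg.scale_factor
    )
    return ds.with_matrix(values, "lognorm")


def hvg_scores(matrix: np.ndarray) -> np.ndarray:
    """vst-style variability score per gene.

    A lowess trend of log10 variance on log10 mean gives each gene its
    expected standard deviation; values are standardised by that expected
    sd, clipped at sqrt(N), and the variance of the clipped values is the
    score. Genes above the trend (more variable than their expression level
    predicts) score high; constant genes score 0 and rank last.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    n = matrix.shape[0]
    mean = matrix.mean(axis=0)
    var = matrix.var(axis=0)
    scores = np.zeros(matrix.shape[1])
    ok = (var > 0) & (mean > 0)
    if not np.any(ok):
        return scores
    log_mean = np.log10(mean[ok])
    log_var = np.log10(var[ok])
    if np.ptp(log_mean) == 0:  # all genes at one mean: flat trend
        expected_sd = np.sqrt(10 ** np.full(log_var.shape, log_var.mean()))
    else:
        # span 0.3 as in the standard vst, widened so the local window
        # always covers enough genes to smooth rather than interpolate
        frac = min(1.0, max(0.3, 50.0 / ok.sum()))
        fit = lowess(
            log_var, log_mean, frac=frac, return_sorted=False, is_sorted=False
        )
        expected_sd = np.sqrt(10**fit)
    z = (matrix[:, ok] - mean[ok]) / expected_sd
    np.clip(z, -np.sqrt(n), np.sqrt(n), out=z)
    scores[ok] = z.var(axis=0)
    return scores


def select_hvg(
    source: ExpressionDataset,
    target: ExpressionDataset,
    cfg: PreprocessConfig | None = None,
) -> tuple[ExpressionDataset, ExpressionDataset, list[str]]:
    """Keep the top n_hvg most variable genes, identically ordered in both.

    Variability is ranked on the `hvg_reference` data (source only by
    default, so the unlabelled query never influences feature selection).
    Ties break lexicographically by gene name.
    """
    cfg = cfg or PreprocessConfig()
    if source.gene_names != target.gene_names:
        raise ValueError("datasets must share the same gene set and order")
    for ds in (source, target):
        if ds.layer not in ("lognorm", "tpm"):
            raise ValueError(
                f"select_hvg expects normalised data, got layer {ds.layer!r}"
            )
    if cfg.n_hvg > source.n_genes:
        raise ValueError(
            f"n_hvg={cfg.n_hvg} exceeds the {source.n_genes} shared genes"
        )
    if cfg.hvg_reference == "source":
        ref = source.matrix
    else:
        ref = np.vstack([source.matrix, target.matrix])
    scores = hvg_scores(ref)
    order = sorted(
        range(source.n_genes), key=lambda i: (-scores[i], source.gene_names[i])
    )
    keep = sorted(order[: cfg.n_hvg])  # preserve original gene order
    genes = [source.gene_names[i] for i in keep]
    return (
        source.subset_genes(keep, layer="hvg"),
        target.subset_genes(keep, layer="hvg"),
        genes,
    )


def resolve_homolog_table(
    pairs: list[tuple[str, str]]
) -> list[tuple[str, str]]:
    """One-to-one mapping: first pair per species-A key by file order wins,
    and pairs re-using an already-claimed species-B gene are dropped."""
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    resolved = []
    for a, b in pairs:
        if a in seen_a or b in seen_b:
            continue
        seen_a.add(a)
        seen_b.add(b)
        resolved.append((a, b))
    return resolved


def intersect_homologs(
    a: ExpressionDataset,
    b: ExpressionDataset,
    table: list[tuple[str, str]],
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Map a's genes through the homolog table onto b's namespace and restrict
    both datasets to the aligned intersection (b's gene names)."""
    if not table:
        raise ValueError("homolog table is empty")
    mapping = dict(resolve_homolog_table(table))
    b_index = {g: i for i, g in enumerate(b.gene_names)}
    a_idx, b_idx, shared = [], [], []
    for i, g in enumerate(a.gene_names):
        mapped = mapping.get(g)
        if mapped is not None and mapped in b_index:
            a_idx.append(i)
            b_idx.append(b_index[mapped])
            shared.append(mapped)
    if not shared:
        raise ValueError("no genes shared after homolog mapping")
    a_out = a.subset_genes(a_idx)
    a_out.gene_names = list(shared)  # adopt b's namespace
    return a_out, b.subset_genes(b_idx)


def preprocess_pair(
    source: ExpressionDataset,
    target: ExpressionDataset,
    cfg: PreprocessConfig | None = None,
    homolog_table: list[tuple[str, str]] | None = None,
) -> tuple[ExpressionDataset, ExpressionDataset, list[str]]:
    """Full preprocessing: optional homolog mapping, shared-gene restriction,
    log-scale normalisation, HVG selection. Returns HVG-layer datasets."""
    cfg = cfg or PreprocessConfig()
    if homolog_table is not None:
        source, target = intersect_homologs(source, target, homolog_table)
    elif source.gene_names != target.gene_names:
        shared = [g for g in source.gene_names if g in set(target.gene_names)]
        if not shared:
            raise ValueError("no genes shared between source and target")
        t_index = {g: i for i, g in enumerate(target.gene_names)}
        s_index = {g: i for i, g in enumerate(source.gene_names)}
        source = source.subset_genes([s_index[g] for g in shared])
        target = target.subset_genes([t_index[g] for g in shared])
    if cfg.normalization == "tpm":
        # depth-normalise then move to log scale for the network input
        s_tpm, t_tpm = tpm_normalize(source), tpm_normalize(target)
        source = s_tpm.with_matrix(np.log1p(s_tpm.matrix), "lognorm")
        target = t_tpm.with_matrix(np.log1p(t_tpm.matrix), "lognorm")
    else:
        source = lognorm(source, cfg)
        target = lognorm(target, cfg)
    return select_hvg(source, target, cfg)
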