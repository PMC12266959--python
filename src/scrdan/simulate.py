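"""Two-batch synthetic scRNA-seq data with a tunable batch effect.

A reduced Splat-style generative model: baseline gene means are Gamma
distributed, each cell group up/down-regulates a fraction of genes through
log-normal differential-expression factors, and each batch multiplies every
gene by its own log-normal batch factor. Library sizes are log-normal and
counts are Poisson. A single intensity knob (applied to both the location
and the scale of the batch factors) controls how strong the batch effect is,
so label transfer can be stressed from trivial to severe.

Compared to the full Splat model there is no dropout layer and no
mean-variance (BCV) trend: group structure plus a tunable batch shift is all
the downstream adversarial training experiments require.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import ExpressionDataset


@dataclass
class SimulationParams:
    """Knobs of the generative model (defaults follow the study conditions:
    10 000 genes, 2000 source + 1000 target cells, four equally likely
    groups, weak DE signal with log-normal scale 0.2)."""

    n_genes: int = 10_000
    n_source_cells: int = 2_000
    n_target_cells: int = 1_000
    n_groups: int = 4
    batch_fac_loc: float = 0.2
    batch_fac_scale: float = 0.2
    de_prob: float = 0.1
    de_fac_scale: float = 0.2
    lib_loc: float = 11.0
    lib_scale: float = 0.2
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    group_probs: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_source_cells", "n_target_cells", "n_groups"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_groups > self.n_source_cells:
            raise ValueError("more groups than source cells")
        if self.batch_fac_loc < 0 or self.batch_fac_scale < 0:
            raise ValueError("batch factor location/scale must be >= 0")
        if not (0 < self.de_prob <= 1):
            raise ValueError("de_prob must be in (0, 1]")
        if self.de_fac_scale < 0 or self.lib_scale < 0:
            raise ValueError("scales must be >= 0")
        if self.group_probs is None:
            self.group_probs = tuple([1.0 / self.n_groups] * self.n_groups)
        else:
            self.group_probs = tuple(float(p) for p in self.group_probs)
        if len(self.group_probs) != self.n_groups:
            raise ValueError("group_probs length must equal n_groups")
        if abs(sum(self.group_probs) - 1.0) > 1e-9:
            raise ValueError("group_probs must sum to 1")

    def with_intensity(self, intensity: float) -> "SimulationParams":
        """Set batch_fac_loc = batch_fac_scale = intensity (the single knob)."""
        return replace(self, batch_fac_loc=intensity, batch_fac_scale=intensity)


GROUP_PREFIX = "Group"


def _simulate_batch(
    rng: np.random.Generator,
    params: SimulationParams,
    base_means: np.ndarray,
    de_factors: np.ndarray,
    batch_factors: np.ndarray,
    n_cells: int,
    domain: str,
    id_prefix: str,
) -> ExpressionDataset:
    groups = rng.choice(params.n_groups, size=n_cells, p=params.group_probs)
    lib_sizes = rng.lognormal(params.lib_loc, params.lib_scale, size=n_cells)
    # expected expression: library size times the cell's normalised gene weights
    weights = base_means[None, :] * de_factors[groups] * batch_factors[None, :]
    weights /= weights.sum(axis=1, keepdims=True)
    counts = rng.poisson(lib_sizes[:, None] * weights)
    return ExpressionDataset(
        matrix=counts,
        gene_names=[f"Gene{g + 1}" for g in range(params.n_genes)],
        cell_ids=[f"{id_prefix}{c + 1}" for c in range(n_cells)],
        domain=domain,
        layer="counts",
        labels=[f"{GROUP_PREFIX}{g + 1}" for g in groups],
    )


def simulate_pair(
    params: SimulationParams,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Generate a (source, target) pair of count datasets sharing genes.

    Group (cell type) identity modulates DE factors identically in both
    batches; only the batch factors differ, so any systematic cross-batch
    expression shift is the simulated batch effect. Target labels are
    generated as ground truth for evaluation; the trainer never reads them.
    """
    rng = np.random.default_rng(params.seed)
    base_means = rng.gamma(params.mean_shape, 1.0 / params.mean_rate, size=params.n_genes)

    # per-group DE: a de_prob fraction of genes gets a log-normal factor with
    # a random up/down direction, the rest stay at 1
    de_factors = np.ones((params.n_groups, params.n_genes))
    for k in range(params.n_groups):
        de_mask = rng.random(params.n_genes) < params.de_prob
        signs = rng.choice([-1.0, 1.0], size=params.n_genes)
        magnitudes = np.abs(rng.normal(0.0, params.de_fac_scale, size=params.n_genes))
        de_factors[k, de_mask] = np.exp(signs[de_mask] * magnitudes[de_mask])

    # per-batch factors: exp(Normal(loc * s, scale)) with a random sign s per
    # gene per batch (symmetric up/down shifts, Splat-style)
    batch_factors = []
    for _ in range(2):
        signs = rng.choice([-1.0, 1.0], size=params.n_genes)
        draws = rng.normal(params.batch_fac_loc * signs, params.batch_fac_scale)
        batch_factors.append(np.exp(draws))

    source = _simulate_batch(
        rng, params, base_means, de_factors, batch_factors[0],
        params.n_source_cells, "source", "SrcCell",
    )
    target = _simulate_batch(
        rng, params, base_means, de_factors, batch_factors[1],
        params.n_target_cells, "target", "TgtCell",
    )
    return source, target


def sweep_intensities(
    base: SimulationParams,
    intensities: list[float],
    replicates: int = 5,
) -> list[tuple[float, int, ExpressionDataset, ExpressionDataset]]:
    """Simulate `replicates` pairs at each batch-effect intensity.

    Replicate seeds are derived as base.seed + 1000 * intensity_index +
    replicate_index, so sweeps are reproducible and non-overlapping.
    """
    if not intensities:
        raise ValueError("intensities must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    out = []
    for i, intensity in enumerate(intensities):
        for r in range(replicates):
            params = replace(
                base.with_intensity(intensity), seed=base.seed + 1000 * i + r
            )
            source, target = simulate_pair(params)
            out.append((intensity, r, source, target))
    return out
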