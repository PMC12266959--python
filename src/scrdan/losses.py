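"""Loss terms of the robust domain-adaptation objective.

The total objective combines three groups of terms:

* denoising domain adaptation: reconstruction MSE on both domains (L_mse),
  cross-entropy on labelled source cells (L_CE), and the adversarial domain
  discrimination loss (L_DA) routed through the gradient reversal layer;
  L_DDANN = L_CE + lambda_DA * L_DA + lambda_mse * L_mse
* fine-grained discrimination: a batch-hard triplet loss (L_tri) where each
  anchor is paired with its farthest same-type cell and its closest
  different-type cell in the embedding space;
* robustness enhancement: a consistency loss between a cell and two
  feature-dropout views of it (L_con) and a virtual adversarial training
  loss on the target domain (L_vat);
  L_CV = L_con + lambda_vat * L_vat

L_total = L_DDANN + L_tri + L_CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import nn
from .nn import Tensor

LOG_EPS = 1e-12  # clamp for log arguments; far below any meaningful probability


@dataclass
class LossWeights:
    """Weights and knobs of the loss terms (defaults are the selected
    hyperparameter combination: lambda_DA=2, lambda_mse=1, lambda_vat=1)."""

    lambda_da: float = 2.0
    lambda_mse: float = 1.0
    lambda_vat: float = 1.0
    margin_alpha: float = 1.0
    consistency_dropout_p: float = 0.2
    vat_epsilon: float = 1.0
    vat_candidates: int = 10

    def __post_init__(self) -> None:
        if min(self.lambda_da, self.lambda_mse, self.lambda_vat) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.margin_alpha <= 0:
            raise ValueError("margin_alpha must be > 0")
        if not (0 < self.consistency_dropout_p < 1):
            raise ValueError("consistency_dropout_p must be in (0, 1)")
        if self.vat_epsilon < 0:
            raise ValueError("vat_epsilon must be >= 0")
        if self.vat_candidates < 1:
            raise ValueError("vat_candidates must be >= 1")


@dataclass
class TripletIndices:
    anchor: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    positive: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    negative: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    def __len__(self) -> int:
        return len(self.anchor)


# ---------------------------------------------------------------------------
# Denoising domain adaptation losses
# ---------------------------------------------------------------------------


def reconstruction_loss(Xs, Xs_rec, Xt, Xt_rec) -> Tensor:
    """Per-domain mean over cells of the squared reconstruction residual
    (summed over genes), added across the two domains."""
    Xs, Xt = nn.as_tensor(Xs), nn.as_tensor(Xt)
    if Xs.shape != Xs_rec.shape or Xt.shape != Xt_rec.shape:
        raise ValueError("original and reconstructed matrices must match in shape")
    ds = Xs - Xs_rec
    dt = Xt - Xt_rec
    return (ds * ds).sum(axis=1).mean() + (dt * dt).sum(axis=1).mean()


def label_loss(probs, labels: np.ndarray) -> Tensor:
    """Cross-entropy between one-hot labels and predicted probabilities,
    averaged over source cells; probabilities clamped at 1e-12."""
    probs = nn.as_tensor(probs)
    labels = np.asarray(labels, dtype=np.intp)
    if probs.shape[0] != labels.shape[0]:
        raise ValueError("one label per probability row required")
    rows = np.arange(len(labels))
    onehot = np.zeros(probs.shape, dtype=np.float32)
    onehot[rows, labels] = 1.0
    logp = probs.clamp_min(LOG_EPS).log()
    return -(nn.as_tensor(onehot) * logp).sum(axis=1).mean()


def domain_loss(d_source, d_target) -> Tensor:
    """Binary cross-entropy of the domain discriminator: source labelled 1,
    target labelled 0."""
    d_source, d_target = nn.as_tensor(d_source), nn.as_tensor(d_target)
    ls = d_source.clamp_min(LOG_EPS).log().mean()
    lt = (1.0 - d_target).clamp_min(LOG_EPS).log().mean()
    return -ls - lt


# ---------------------------------------------------------------------------
# Fine-grained discrimination
# ---------------------------------------------------------------------------


def mine_triplets(Z, labels: np.ndarray) -> TripletIndices:
    """Batch-hard mining on squared Euclidean embedding distances.

    For every anchor with at least one same-class peer and one other-class
    cell: positive = farthest same-class cell (excluding the anchor itself),
    negative = closest other-class cell. Ties break at the lowest index.
    Anchors lacking either side are skipped; a single-class batch yields an
    empty set.
    """
    Zd = Z.data if isinstance(Z, Tensor) else np.asarray(Z)
    labels = np.asarray(labels)
    n = Zd.shape[0]
    if n != labels.shape[0]:
        raise ValueError("one label per embedding row required")
    dist = cdist(Zd.astype(np.float64), Zd.astype(np.float64), "sqeuclidean")
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)  # anchor may not be its own positive
    diff = labels[:, None] != labels[None, :]

    anchors, positives, negatives = [], [], []
    pos_masked = np.where(same, dist, -np.inf)
    neg_masked = np.where(diff, dist, np.inf)
    has_pos = same.any(axis=1)
    has_neg = diff.any(axis=1)
    for i in range(n):
        if not (has_pos[i] and has_neg[i]):
            continue
        anchors.append(i)
        positives.append(int(np.argmax(pos_masked[i])))
        negatives.append(int(np.argmin(neg_masked[i])))
    return TripletIndices(
        np.asarray(anchors, dtype=np.intp),
        np.asarray(positives, dtype=np.intp),
        np.asarray(negatives, dtype=np.intp),
    )


def triplet_loss(
    Z, triplets: TripletIndices, alpha: float = 1.0, reduction: str = "mean"
) -> Tensor:
    """[d(a,p) - d(a,n) + alpha]_+ over anchors with squared Euclidean
    distances in the embedding space.

    The default per-batch reduction is the mean over mined anchors so the
    term's gradient scale is independent of batch size (standard batch-hard
    practice; an anchor sum is available via reduction="sum").
    """
    Z = nn.as_tensor(Z)
    if len(triplets) == 0:
        return Tensor(0.0)
    za = Z.take_rows(triplets.anchor)
    zp = Z.take_rows(triplets.positive)
    zn = Z.take_rows(triplets.negative)
    dp = ((za - zp) ** 2).sum(axis=1)
    dn = ((za - zn) ** 2).sum(axis=1)
    hinge = (dp - dn + alpha).clamp_min(0.0)
    return hinge.mean() if reduction == "mean" else hinge.sum()


# ---------------------------------------------------------------------------
# Robustness enhancement
# ---------------------------------------------------------------------------


def consistency_masks(
    shape: tuple[int, int], p: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent dropout masks per cell per feature.

    Inverted-dropout convention: kept entries carry 1/(1-p) so each view is
    an unbiased estimate of the clean input and the embedding gap can
    actually be closed."""
    scale = np.float32(1.0 / (1.0 - p))
    m1 = (rng.random(shape) >= p).astype(np.float32) * scale
    m2 = (rng.random(shape) >= p).astype(np.float32) * scale
    return m1, m2


def consistency_loss_from_masks(network, Xs, m1, m2, train: bool = True) -> Tensor:
    """Eq.-level core of the consistency loss with injected masks (used both
    by the training path and by the loop-oracle tests).

    The clean input and both views go through the encoder in a single
    concatenated forward pass so batch-norm statistics are shared; the
    embedding gap then measures feature sensitivity, not batch-statistic
    shifts. Running statistics are left untouched — this auxiliary pass is
    source-only and would otherwise bias them away from the target domain."""
    X = nn.as_tensor(Xs)
    n = X.shape[0]
    stacked = nn.concat_rows([X, X * nn.as_tensor(m1), X * nn.as_tensor(m2)])
    z_all = network.encode(stacked, train=train, update_stats=False)
    z = z_all.take_rows(np.arange(n))
    z1 = z_all.take_rows(np.arange(n, 2 * n))
    z2 = z_all.take_rows(np.arange(2 * n, 3 * n))
    d1 = z - z1
    d2 = z - z2
    return ((d1 * d1).sum(axis=1) + (d2 * d2).sum(axis=1)).mean()


def consistency_loss(
    network, Xs, p: float, rng: np.random.Generator, train: bool = True
) -> Tensor:
    """Mean squared embedding gap between each source cell and two random
    feature-dropout views of it."""
    if not (0 < p < 1):
        raise ValueError("dropout fraction must be in (0, 1)")
    Xd = Xs.data if isinstance(Xs, Tensor) else np.asarray(Xs)
    m1, m2 = consistency_masks(Xd.shape, p, rng)
    return consistency_loss_from_masks(network, Xs, m1, m2, train=train)


def _kl_rows(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    p = np.clip(p, LOG_EPS, None)
    q = np.clip(q, LOG_EPS, None)
    return (p * (np.log(p) - np.log(q))).sum(axis=1)


def vat_loss(
    network,
    Xt,
    epsilon: float = 1.0,
    n_candidates: int = 10,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Virtual adversarial training on the target domain.

    Draws `n_candidates` random unit directions per cell (scaled to radius
    epsilon), picks the candidate whose perturbation maximises
    KL[p(Y|X_t) || p(Y|X_t + r)], and returns that KL with the clean
    distribution treated as a constant. All forwards use the same
    (train-mode, batch-statistic) network configuration as the rest of the
    training step — mixing in eval-mode statistics would let the network
    satisfy the penalty in a configuration the optimiser never trains —
    but running statistics are left untouched.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    rng = rng or np.random.default_rng()
    Xd = Xt.data if isinstance(Xt, Tensor) else np.asarray(Xt, dtype=np.float32)

    def forward(x):
        return network.classify(
            network.encode(x, train=True, update_stats=False), train=True
        )

    with nn.no_grad():
        clean_probs = forward(Xd).data
        best_kl = -np.inf
        best_r = None
        for _ in range(n_candidates):
            d = rng.standard_normal(Xd.shape).astype(np.float32)
            norms = np.linalg.norm(d, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            r = (epsilon / norms) * d
            q = forward(Xd + r).data
            kl = float(_kl_rows(clean_probs, q).mean())
            if kl > best_kl:
                best_kl, best_r = kl, r

    q = forward(Xd + best_r)
    logq = q.clamp_min(LOG_EPS).log()
    p = np.clip(clean_probs, LOG_EPS, None)
    const = float((p * np.log(p)).sum(axis=1).mean())
    return const - (nn.as_tensor(p) * logq).sum(axis=1).mean()


# ---------------------------------------------------------------------------
# Total objective
# ---------------------------------------------------------------------------

COMPONENT_NAMES = ("ce", "da", "mse", "tri", "con", "vat")


def total_loss(
    components: dict[str, Tensor | float], weights: LossWeights
) -> tuple[Tensor, dict[str, float]]:
    """Assemble L_total = L_DDANN + L_tri + L_CV and return the breakdown.

    Missing components (e.g. ablated terms) count as zero. Any NaN aborts
    with the offending component's name.
    """
    terms: dict[str, Tensor] = {}
    for name in COMPONENT_NAMES:
        t = components.get(name, 0.0)
        terms[name] = nn.as_tensor(t)
        if np.isnan(terms[name].data).any():
            raise FloatingPointError(f"loss component {name!r} is NaN")
    w = weights
    ddann = terms["ce"] + w.lambda_da * terms["da"] + w.lambda_mse * terms["mse"]
    cv = terms["con"] + w.lambda_vat * terms["vat"]
    total = ddann + terms["tri"] + cv
    breakdown = {name: float(t.data) for name, t in terms.items()}
    breakdown["ddann"] = float(ddann.data)
    breakdown["cv"] = float(cv.data)
    breakdown["total"] = float(total.data)
    return total, breakdown
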