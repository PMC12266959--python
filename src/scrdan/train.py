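"""Training orchestration: the CellTypeTransfer model and its Results.

`CellTypeTransfer` holds the labelled source dataset, the unlabelled target
dataset and the three config objects; `.fit()` runs the optimisation and
returns a `CellTypeTransferResults` carrying the trained network, the loss
history, and the annotation/evaluation/summary methods.

Each optimisation step draws one batch per domain (independent shuffles,
the smaller domain cycling), encodes both through the shared encoder, and
takes a single SGD step on the weighted total loss. A constant-coefficient
gradient reversal layer routes the adversarial signal, so no alternating
updates are needed. The learning rate follows the inverse-decay schedule
lr0 * (1 + decay * step)^(-power) per optimizer step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import losses as L
from . import nn
from .data import ExpressionDataset
from .evaluate import (
    EvalReport,
    confusion_table,
    evaluate_embeddings,
    mean_class_accuracy,
)
from .losses import LossWeights
from .network import ModelSpec, Network, load_network, save_network

ABLATION_FLAGS = frozenset({"no_mse", "no_da", "no_tri", "no_con", "no_vat"})


@dataclass
class TrainConfig:
    lr0: float = 0.001
    lr_decay: float = 0.001
    lr_power: float = 0.9
    momentum: float = 0.9
    weight_decay: float = 5e-4
    epochs: int = 200
    batch_size: int = 256
    seed: int = 0
    ablation: frozenset[str] = field(default_factory=frozenset)
    early_stop_patience: int = 20
    early_stop_min_delta: float = 1e-4
    grad_clip_norm: float | None = 5.0
    grl_schedule: str = "constant"  # or "dann" (sigmoid warm-up ramp)
    schedule_unit: str = "step"  # or "epoch"
    log_path: str | None = None

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        self.ablation = frozenset(self.ablation)
        unknown = self.ablation - ABLATION_FLAGS
        if unknown:
            raise ValueError(f"unknown ablation flags: {sorted(unknown)}")
        if self.schedule_unit not in ("step", "epoch"):
            raise ValueError("schedule_unit must be 'step' or 'epoch'")
        if self.grl_schedule not in ("constant", "dann"):
            raise ValueError("grl_schedule must be 'constant' or 'dann'")


def lr_at(step: int, cfg: TrainConfig) -> float:
    """Inverse-decay schedule: lr0 * (1 + decay * step)^(-power)."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return cfg.lr0 * (1.0 + cfg.lr_decay * step) ** (-cfg.lr_power)


class CellTypeTransfer:
    """Label-transfer model over a labelled source and unlabelled target."""

    def __init__(
        self,
        source: ExpressionDataset,
        target: ExpressionDataset,
        model_spec: ModelSpec | None = None,
        loss_weights: LossWeights | None = None,
        train_config: TrainConfig | None = None,
    ):
        if source.gene_names != target.gene_names:
            div = next(
                (
                    (a, b)
                    for a, b in zip(source.gene_names, target.gene_names)
                    if a != b
                ),
                None,
            )
            raise ValueError(
                f"source and target gene order differs (first divergence: {div})"
            )
        if source.labels is None:
            raise ValueError("source dataset must carry cell type labels")
        self.source = source
        self.target = target
        self.train_config = train_config or TrainConfig()
        self.loss_weights = loss_weights or LossWeights()
        self.class_names = sorted(set(source.labels))
        k = len(self.class_names)
        if k == 1:
            warnings.warn(
                "source has a single cell type; triplet loss disabled",
                stacklevel=2,
            )
            self.train_config = replace(
                self.train_config,
                ablation=self.train_config.ablation | {"no_tri"},
            )
        self.model_spec = model_spec or ModelSpec(
            input_dim=source.n_genes,
            n_classes=max(k, 2),
            seed=self.train_config.seed,
        )
        if self.model_spec.input_dim != source.n_genes:
            raise ValueError(
                f"model input_dim {self.model_spec.input_dim} != "
                f"{source.n_genes} genes"
            )

    def fit(self, verbose: bool = False) -> "CellTypeTransferResults":
        cfg = self.train_config
        w = self.loss_weights
        abl = cfg.ablation
        rng = np.random.default_rng(cfg.seed)
        network = Network(self.model_spec)
        opt = nn.SGD(
            network.parameters(),
            momentum=cfg.momentum,
            weight_decay=cfg.weight_decay,
        )

        Xs = np.ascontiguousarray(self.source.matrix, dtype=np.float32)
        Xt = np.ascontiguousarray(self.target.matrix, dtype=np.float32)
        class_index = {c: i for i, c in enumerate(self.class_names)}
        ys = np.asarray([class_index[l] for l in self.source.labels], dtype=np.intp)
        ms, mt = Xs.shape[0], Xt.shape[0]
        bs = cfg.batch_size
        steps_per_epoch = max(math.ceil(ms / bs), math.ceil(mt / bs))
        total_steps = steps_per_epoch * cfg.epochs

        history: list[dict[str, float]] = []
        best_total = np.inf
        best_state: list[np.ndarray] | None = None
        best_epoch = -1
        patience = 0
        global_step = 0

        for epoch in range(cfg.epochs):
            perm_s = rng.permutation(ms)
            perm_t = rng.permutation(mt)
            sums: dict[str, float] = {}
            for step in range(steps_per_epoch):
                lo = step * bs
                s_idx = perm_s.take(np.arange(lo, lo + bs), mode="wrap")
                t_idx = perm_t.take(np.arange(lo, lo + bs), mode="wrap")
                Xb_s = nn.Tensor(Xs[s_idx])
                Xb_t = nn.Tensor(Xt[t_idx])
                ns = Xb_s.shape[0]

                Z = network.encode(nn.concat_rows([Xb_s, Xb_t]), train=True)
                Z_s = Z.take_rows(np.arange(ns))
                Z_t = Z.take_rows(np.arange(ns, Z.shape[0]))

                # the reconstruction, triplet and consistency terms are
                # per-cell vector norms over hundreds of dimensions; for
                # optimisation they are averaged per dimension so every
                # term enters the gradient at a comparable O(1) scale
                # (the standard elementwise-mean framework reduction)
                components: dict[str, nn.Tensor] = {}
                probs = network.classify(Z_s, train=True)
                components["ce"] = L.label_loss(probs, ys[s_idx])
                if "no_mse" not in abl:
                    rec = network.decode(Z, train=True)
                    components["mse"] = L.reconstruction_loss(
                        Xb_s,
                        rec.take_rows(np.arange(ns)),
                        Xb_t,
                        rec.take_rows(np.arange(ns, Z.shape[0])),
                    ) * (1.0 / self.model_spec.input_dim)
                if "no_da" not in abl:
                    lam = self.model_spec.grl_lambda
                    if cfg.grl_schedule == "dann":
                        # sigmoid ramp 0 -> grl_lambda so early noisy
                        # features are not adversarially scrambled
                        prog = global_step / max(total_steps - 1, 1)
                        lam *= 2.0 / (1.0 + math.exp(-10.0 * prog)) - 1.0
                    d_s = network.discriminate(
                        network.grl_apply(Z_s, lam), train=True
                    )
                    d_t = network.discriminate(
                        network.grl_apply(Z_t, lam), train=True
                    )
                    components["da"] = L.domain_loss(d_s, d_t)
                if "no_tri" not in abl:
                    triplets = L.mine_triplets(Z_s, ys[s_idx])
                    components["tri"] = L.triplet_loss(
                        Z_s, triplets, alpha=w.margin_alpha
                    ) * (1.0 / self.model_spec.latent_dim)
                if "no_con" not in abl:
                    components["con"] = L.consistency_loss(
                        network, Xb_s, w.consistency_dropout_p, rng, train=True
                    ) * (1.0 / self.model_spec.latent_dim)
                if "no_vat" not in abl:
                    components["vat"] = L.vat_loss(
                        network,
                        Xb_t.data,
                        epsilon=w.vat_epsilon,
                        n_candidates=w.vat_candidates,
                        rng=rng,
                    )

                total, breakdown = L.total_loss(components, w)
                opt.zero_grad()
                total.backward()
                if cfg.grad_clip_norm is not None:
                    nn.clip_grad_norm(network.parameters(), cfg.grad_clip_norm)
                sched_step = epoch if cfg.schedule_unit == "epoch" else global_step
                opt.step(lr_at(sched_step, cfg))
                global_step += 1
                for k, v in breakdown.items():
                    sums[k] = sums.get(k, 0.0) + v

            means = {k: v / steps_per_epoch for k, v in sums.items()}
            # plateau/checkpoint criterion: the domain loss rises by design
            # as the encoder wins the adversarial game, so convergence is
            # judged on the remaining (jointly minimised) terms
            means["objective"] = means["total"] - w.lambda_da * means.get("da", 0.0)
            means["epoch"] = epoch
            means["lr"] = lr_at(
                epoch if cfg.schedule_unit == "epoch" else global_step - 1, cfg
            )
            history.append(means)
            if verbose:
                print(
                    f"epoch {epoch}: total={means['total']:.4f} "
                    f"ce={means['ce']:.4f}"
                )

            if means["objective"] < best_total - cfg.early_stop_min_delta:
                best_total = means["objective"]
                best_state = network.snapshot()
                best_epoch = epoch
                patience = 0
            else:
                patience += 1
                if patience >= cfg.early_stop_patience:
                    break

        if best_state is not None:
            network.load_snapshot(best_state)

        hist = pd.DataFrame(history)
        if cfg.log_path:
            cols = ["epoch"] + [c for c in hist.columns if c != "epoch"]
            hist[cols].to_csv(cfg.log_path, sep="\t", index=False)

        return CellTypeTransferResults(
            model=self,
            network=network,
            class_names=self.class_names,
            gene_names=list(self.source.gene_names),
            history=hist,
            best_epoch=best_epoch,
        )


class CellTypeTransferResults:
    """Trained parameters plus annotation, evaluation and persistence."""

    def __init__(
        self,
        network: Network,
        class_names: list[str],
        gene_names: list[str],
        model: CellTypeTransfer | None = None,
        history: pd.DataFrame | None = None,
        best_epoch: int = -1,
    ):
        self.model = model
        self.network = network
        self.class_names = list(class_names)
        self.gene_names = list(gene_names)
        self.history = history if history is not None else pd.DataFrame()
        self.best_epoch = best_epoch

    # -- inference ------------------------------------------------------------
    def _check_genes(self, ds: ExpressionDataset) -> None:
        if ds.gene_names != self.gene_names:
            div = next(
                (
                    (i, a, b)
                    for i, (a, b) in enumerate(zip(ds.gene_names, self.gene_names))
                    if a != b
                ),
                ("length", len(ds.gene_names), len(self.gene_names)),
            )
            raise ValueError(
                f"gene order differs from training genes (first divergence: {div})"
            )

    def embed(self, ds: ExpressionDataset) -> np.ndarray:
        """Latent embedding of a dataset (eval mode, deterministic)."""
        self._check_genes(ds)
        X = np.ascontiguousarray(ds.matrix, dtype=np.float32)
        return self.network.encode(X, train=False).data.copy()

    def annotate(
        self, target: ExpressionDataset | None = None
    ) -> tuple[pd.DataFrame, np.ndarray]:
        """Predicted type and class probabilities per target cell, plus the
        latent embeddings. Argmax ties break at the lowest class index."""
        if target is None:
            if self.model is None:
                raise ValueError("no target dataset attached; pass one explicitly")
            target = self.model.target
        self._check_genes(target)
        X = np.ascontiguousarray(target.matrix, dtype=np.float32)
        Z = self.network.encode(X, train=False)
        probs = self.network.classify(Z, train=False).data
        pred_idx = probs.argmax(axis=1)
        names = self.class_names + [
            f"unused_{i}" for i in range(len(self.class_names), probs.shape[1])
        ]
        df = pd.DataFrame(
            {
                "cell_id": target.cell_ids,
                "predicted_type": [names[i] for i in pred_idx],
            }
        )
        for i, name in enumerate(names):
            df[f"prob_{name}"] = probs[:, i]
        return df, Z.data.copy()

    # -- evaluation -----------------------------------------------------------
    def evaluate(
        self,
        source: ExpressionDataset | None = None,
        target: ExpressionDataset | None = None,
        truth_target: list[str] | None = None,
    ) -> EvalReport:
        if source is None or target is None:
            if self.model is None:
                raise ValueError("no datasets attached; pass them explicitly")
            source = source or self.model.source
            target = target or self.model.target
        return evaluate_run(self, source, target, truth_target)

    def summary(self) -> str:
        lines = [
            "CellTypeTransfer results",
            "=" * 48,
            f"genes (input features): {len(self.gene_names)}",
            f"cell types:             {len(self.class_names)} "
            f"({', '.join(self.class_names[:6])}"
            + (", ..." if len(self.class_names) > 6 else "")
            + ")",
            f"latent dimension:       {self.network.spec.latent_dim}",
            f"epochs run:             {len(self.history)}",
            f"best epoch (objective): {self.best_epoch}",
        ]
        if len(self.history):
            last = self.history.iloc[-1]
            lines.append("final epoch losses:")
            for k in ("ce", "da", "mse", "tri", "con", "vat", "total"):
                if k in last:
                    lines.append(f"  {k:>5s}: {last[k]:.4f}")
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        extra = {
            "class_names": self.class_names,
            "gene_names": self.gene_names,
            "best_epoch": self.best_epoch,
            "history": self.history.to_dict(orient="list"),
        }
        save_network(path, self.network, extra)

    @classmethod
    def load(cls, path) -> "CellTypeTransferResults":
        network, extra = load_network(path)
        return cls(
            network=network,
            class_names=extra["class_names"],
            gene_names=extra["gene_names"],
            history=pd.DataFrame(extra.get("history", {})),
            best_epoch=extra.get("best_epoch", -1),
        )


# Back-compatible names for the functional interface.
TrainedModel = CellTypeTransferResults


def train(
    source: ExpressionDataset,
    target: ExpressionDataset,
    model_spec: ModelSpec | None = None,
    loss_weights: LossWeights | None = None,
    cfg: TrainConfig | None = None,
    verbose: bool = False,
) -> CellTypeTransferResults:
    """Functional wrapper: build a CellTypeTransfer and fit it."""
    return CellTypeTransfer(
        source, target, model_spec=model_spec, loss_weights=loss_weights,
        train_config=cfg,
    ).fit(verbose=verbose)


def annotate(
    model: CellTypeTransferResults, target: ExpressionDataset
) -> tuple[pd.DataFrame, np.ndarray]:
    return model.annotate(target)


def evaluate_run(
    results: CellTypeTransferResults,
    source: ExpressionDataset,
    target: ExpressionDataset,
    truth_target: list[str] | None = None,
) -> EvalReport:
    """Full evaluation: target annotation accuracy plus joint-embedding
    silhouettes (cell types as clusters; batch silhouette as diagnostic)."""
    pred_df, Zt = results.annotate(target)
    predicted = list(pred_df["predicted_type"])
    Zs = results.embed(source)
    truth = truth_target if truth_target is not None else target.labels

    if truth is not None:
        per_class, mean_acc = mean_class_accuracy(predicted, truth)
        confusion = confusion_table(predicted, truth)
        target_types = list(truth)
    else:
        warnings.warn(
            "no target truth available; accuracy omitted and silhouette "
            "falls back to predicted labels",
            stacklevel=2,
        )
        per_class, mean_acc, confusion = None, None, None
        target_types = predicted

    if source.labels is None:
        raise ValueError("source dataset must carry labels for evaluation")
    sil_type, sil_batch = evaluate_embeddings(Zs, Zt, source.labels, target_types)
    return EvalReport(
        per_class_accuracy=per_class,
        mean_accuracy=mean_acc,
        silhouette_celltype=sil_type,
        silhouette_batch=sil_batch,
        confusion=confusion,
        n_source_cells=source.n_cells,
        n_target_cells=target.n_cells,
    )
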