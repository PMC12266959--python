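"""The four-component annotation network.

An encoder E maps log-normalised expression profiles of both domains into a
shared latent space; a decoder D reconstructs the input from the latent code
(denoising); a label classifier F predicts cell types from the latent code;
and a domain discriminator Do, fed through a gradient reversal layer, drives
the adversarial alignment of source and target latent distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .nn import MLP, Tensor, grad_reverse


@dataclass
class ModelSpec:
    """Architecture hyperparameters.

    input_dim is the number of genes after HVG selection; latent_dim is the
    width of the last encoder layer. grl_lambda is the gradient-reversal
    coefficient lamd (kept constant during training by default).
    """

    input_dim: int
    n_classes: int
    encoder_dims: tuple[int, ...] = (512, 256)
    decoder_dims: tuple[int, ...] | None = None  # None -> mirror of encoder
    classifier_dims: tuple[int, ...] = ()
    discriminator_dims: tuple[int, ...] = (128,)
    grl_lambda: float = 2.0
    batchnorm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim <= 0:
            raise ValueError("input_dim must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.grl_lambda < 0:
            raise ValueError("grl_lambda must be >= 0")
        self.encoder_dims = tuple(self.encoder_dims)
        if self.decoder_dims is None:
            self.decoder_dims = tuple(reversed(self.encoder_dims[:-1])) + (
                self.input_dim,
            )
        else:
            self.decoder_dims = tuple(self.decoder_dims)
        self.classifier_dims = tuple(self.classifier_dims)
        self.discriminator_dims = tuple(self.discriminator_dims)

    @property
    def latent_dim(self) -> int:
        return self.encoder_dims[-1]

    def to_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "n_classes": self.n_classes,
            "encoder_dims": list(self.encoder_dims),
            "decoder_dims": list(self.decoder_dims),
            "classifier_dims": list(self.classifier_dims),
            "discriminator_dims": list(self.discriminator_dims),
            "grl_lambda": self.grl_lambda,
            "batchnorm": self.batchnorm,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        for k in ("encoder_dims", "decoder_dims", "classifier_dims", "discriminator_dims"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


class Network:
    """Encoder/decoder/classifier/discriminator with shared seeding."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        s = spec
        # batchnorm+ReLU on every encoder layer: pinning the latent scale
        # blocks the trivial collapse Z -> 0 that the consistency term
        # would otherwise admit
        self.encoder = MLP(
            (s.input_dim, *s.encoder_dims), rng, batchnorm=s.batchnorm,
            final_activation=True,
        )
        self.decoder = MLP(
            (s.latent_dim, *s.decoder_dims), rng, batchnorm=s.batchnorm,
        )
        self.classifier = MLP(
            (s.latent_dim, *s.classifier_dims, s.n_classes), rng, batchnorm=False,
        )
        self.discriminator = MLP(
            (s.latent_dim, *s.discriminator_dims, 1), rng, batchnorm=False,
        )

    # -- forward passes -------------------------------------------------------
    def encode(
        self, X, train: bool = False, update_stats: bool = True
    ) -> Tensor:
        X = nn.as_tensor(X)
        if X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"expected {self.spec.input_dim} input features, got {X.shape[1]}"
            )
        return self.encoder(X, train=train, update_stats=update_stats)

    def decode(self, Z: Tensor, train: bool = False) -> Tensor:
        Z = nn.as_tensor(Z)
        if Z.shape[1] != self.spec.latent_dim:
            raise ValueError(
                f"expected {self.spec.latent_dim} latent features, got {Z.shape[1]}"
            )
        return self.decoder(Z, train=train)

    def classify_logits(self, Z: Tensor, train: bool = False) -> Tensor:
        Z = nn.as_tensor(Z)
        if Z.shape[1] != self.spec.latent_dim:
            raise ValueError(
                f"expected {self.spec.latent_dim} latent features, got {Z.shape[1]}"
            )
        return self.classifier(Z, train=train)

    def classify(self, Z: Tensor, train: bool = False) -> Tensor:
        """Class probability rows (softmax over the K cell types)."""
        return nn.softmax(self.classify_logits(Z, train=train))

    def discriminate(self, Z: Tensor, train: bool = False) -> Tensor:
        """P(domain == source) per cell, in (0, 1)."""
        Z = nn.as_tensor(Z)
        if Z.shape[1] != self.spec.latent_dim:
            raise ValueError(
                f"expected {self.spec.latent_dim} latent features, got {Z.shape[1]}"
            )
        return self.discriminator(Z, train=train).sigmoid()

    def grl_apply(self, Z: Tensor, lam: float | None = None) -> Tensor:
        """Gradient reversal with the spec's lamd (overridable)."""
        return grad_reverse(Z, self.spec.grl_lambda if lam is None else lam)

    # -- parameter plumbing ---------------------------------------------------
    def parameters(self) -> list[nn.Parameter]:
        return (
            self.encoder.parameters()
            + self.decoder.parameters()
            + self.classifier.parameters()
            + self.discriminator.parameters()
        )

    def state_arrays(self) -> list[np.ndarray]:
        return (
            self.encoder.state()
            + self.decoder.state()
            + self.classifier.state()
            + self.discriminator.state()
        )

    def component_state(self, name: str) -> list[np.ndarray]:
        return [a.copy() for a in getattr(self, name).state()]

    def snapshot(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def load_snapshot(self, arrays: Sequence[np.ndarray]) -> None:
        it = iter(arrays)
        for comp in (self.encoder, self.decoder, self.classifier, self.discriminator):
            n = len(comp.state())
            comp.load_state([next(it) for _ in range(n)])


def save_network(path, network: Network, extra: dict | None = None) -> None:
    """Serialise spec + weights (+ JSON-serialisable extras) to one .npz file."""
    meta = {"spec": network.spec.to_dict(), "extra": extra or {}}
    arrays = {f"arr_{i}": a for i, a in enumerate(network.state_arrays())}
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_network(path) -> tuple[Network, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    network = Network(ModelSpec.from_dict(meta["spec"]))
    network.load_snapshot(arrays)
    return network, meta["extra"]
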