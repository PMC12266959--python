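"""Training orchestration: schedule, determinism, gradient routing,
annotation contracts, and the Results object."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from scrdan.evaluate import mean_class_accuracy
from scrdan.losses import LossWeights
from scrdan.network import ModelSpec
from scrdan.train import (
    CellTypeTransfer,
    CellTypeTransferResults,
    TrainConfig,
    evaluate_run,
    lr_at,
    train,
)

SMALL_SPEC = dict(encoder_dims=(32, 16), discriminator_dims=(8,))


def quick_config(**kw):
    base = dict(epochs=8, batch_size=64, seed=0)
    base.update(kw)
    return TrainConfig(**base)


def small_spec(n_genes, n_classes=4, seed=0):
    return ModelSpec(input_dim=n_genes, n_classes=n_classes, seed=seed, **SMALL_SPEC)


@pytest.fixture(scope="module")
def fitted(tiny_hvg_pair, tiny_unlabeled_target):
    sp, tp, _ = tiny_hvg_pair
    model = CellTypeTransfer(
        sp,
        tiny_unlabeled_target,
        model_spec=small_spec(sp.n_genes),
        train_config=TrainConfig(epochs=30, batch_size=64, seed=0),
    )
    return model.fit()


class TestSchedule:
    def test_initial_rate(self):
        assert lr_at(0, TrainConfig()) == pytest.approx(0.001)

    def test_hand_evaluation_at_step_1000(self):
        # 0.001 * (1 + 0.001*1000)^-0.9 = 0.001 * 2^-0.9
        assert lr_at(1000, TrainConfig()) == pytest.approx(
            0.001 * 2 ** -0.9, rel=1e-9
        )

    def test_monotone_decreasing(self):
        cfg = TrainConfig()
        rates = [lr_at(s, cfg) for s in range(0, 10_000, 97)]
        assert all(a > b for a, b in zip(rates, rates[1:]))
        assert all(r > 0 for r in rates)

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError):
            lr_at(-1, TrainConfig())


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lr0": 0.0},
            {"batch_size": 1},
            {"epochs": 0},
            {"ablation": frozenset({"no_everything"})},
            {"grl_schedule": "linear"},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)


class TestFitContracts:
    def test_mismatched_gene_order_rejected(self, tiny_hvg_pair):
        sp, tp, _ = tiny_hvg_pair
        flipped = dataclasses.replace(
            tp,
            matrix=tp.matrix[:, ::-1],
            gene_names=list(reversed(tp.gene_names)),
            labels=None,
        )
        with pytest.raises(ValueError, match="gene order"):
            CellTypeTransfer(sp, flipped)

    def test_unlabeled_source_rejected(self, tiny_hvg_pair):
        sp, tp, _ = tiny_hvg_pair
        with pytest.raises(ValueError, match="labels"):
            CellTypeTransfer(dataclasses.replace(sp, labels=None), tp)

    def test_single_class_source_warns_and_disables_triplet(self, tiny_hvg_pair):
        sp, tp, _ = tiny_hvg_pair
        mono = dataclasses.replace(sp, labels=["T"] * sp.n_cells)
        with pytest.warns(UserWarning, match="triplet"):
            model = CellTypeTransfer(
                mono, dataclasses.replace(tp, labels=None)
            )
        assert "no_tri" in model.train_config.ablation

    def test_same_seed_gives_bit_identical_models(
        self, tiny_hvg_pair, tiny_unlabeled_target
    ):
        sp, _, _ = tiny_hvg_pair
        runs = [
            train(
                sp,
                tiny_unlabeled_target,
                model_spec=small_spec(sp.n_genes),
                cfg=quick_config(),
            )
            for _ in range(2)
        ]
        for a, b in zip(
            runs[0].network.state_arrays(), runs[1].network.state_arrays()
        ):
            np.testing.assert_array_equal(a, b)

    def test_different_seed_differs(self, tiny_hvg_pair, tiny_unlabeled_target):
        sp, _, _ = tiny_hvg_pair
        a = train(
            sp, tiny_unlabeled_target,
            model_spec=small_spec(sp.n_genes), cfg=quick_config(seed=0),
        )
        b = train(
            sp, tiny_unlabeled_target,
            model_spec=small_spec(sp.n_genes, seed=1), cfg=quick_config(seed=1),
        )
        assert any(
            not np.array_equal(x, y)
            for x, y in zip(a.network.state_arrays(), b.network.state_arrays())
        )


class TestGradientRouting:
    def _fit(self, pair, target, ablation):
        sp, _, _ = pair
        model = CellTypeTransfer(
            sp,
            target,
            model_spec=small_spec(sp.n_genes),
            train_config=quick_config(epochs=3, ablation=ablation),
        )
        net_before = model.model_spec
        results = model.fit()
        return results

    def test_no_da_leaves_discriminator_untouched(
        self, tiny_hvg_pair, tiny_unlabeled_target
    ):
        res = self._fit(tiny_hvg_pair, tiny_unlabeled_target, frozenset({"no_da"}))
        from scrdan.network import Network

        virgin = Network(res.network.spec)
        for a, b in zip(
            res.network.discriminator.state(), virgin.discriminator.state()
        ):
            np.testing.assert_array_equal(a, b)
        # encoder did train
        assert any(
            not np.array_equal(a, b)
            for a, b in zip(res.network.encoder.state(), virgin.encoder.state())
        )

    def test_no_mse_leaves_decoder_untouched(
        self, tiny_hvg_pair, tiny_unlabeled_target
    ):
        res = self._fit(tiny_hvg_pair, tiny_unlabeled_target, frozenset({"no_mse"}))
        from scrdan.network import Network

        virgin = Network(res.network.spec)
        for a, b in zip(res.network.decoder.state(), virgin.decoder.state()):
            np.testing.assert_array_equal(a, b)


class TestTrainingBehaviour:
    def test_loss_decreases_over_training(self, fitted):
        hist = fitted.history
        assert hist.iloc[-1]["objective"] < hist.iloc[0]["objective"]

    def test_source_accuracy_beats_chance_after_training(
        self, fitted, tiny_hvg_pair
    ):
        sp, _, _ = tiny_hvg_pair
        pred, _ = fitted.annotate(sp)
        _, acc = mean_class_accuracy(list(pred["predicted_type"]), sp.labels)
        assert acc > 0.5  # chance is 0.25 for four groups

    def test_discriminator_confused_by_the_end(self, fitted, tiny_hvg_pair,
                                               tiny_unlabeled_target):
        """Adversarial direction: after training, the discriminator should
        separate domains worse than a freshly trained discriminator would
        at the start — final domain loss above the perfect-separation 0."""
        hist = fitted.history
        assert hist.iloc[-1]["da"] > 0.1


class TestAnnotateAndResults:
    def test_probabilities_sum_to_one_and_deterministic(
        self, fitted, tiny_unlabeled_target
    ):
        pred1, emb1 = fitted.annotate(tiny_unlabeled_target)
        pred2, emb2 = fitted.annotate(tiny_unlabeled_target)
        prob_cols = [c for c in pred1.columns if c.startswith("prob_")]
        np.testing.assert_allclose(
            pred1[prob_cols].sum(axis=1), 1.0, atol=1e-5
        )
        pd.testing.assert_frame_equal(pred1, pred2)
        np.testing.assert_array_equal(emb1, emb2)

    def test_annotate_rejects_wrong_genes(self, fitted, tiny_unlabeled_target):
        broken = dataclasses.replace(
            tiny_unlabeled_target,
            matrix=tiny_unlabeled_target.matrix[:, :-1],
            gene_names=tiny_unlabeled_target.gene_names[:-1],
        )
        with pytest.raises(ValueError, match="gene"):
            fitted.annotate(broken)

    def test_evaluate_run_report_is_complete(self, fitted, tiny_hvg_pair):
        sp, tp, _ = tiny_hvg_pair
        report = evaluate_run(fitted, sp, tp)
        assert set(report.per_class_accuracy) == set(sp.labels)
        assert 0 <= report.mean_accuracy <= 1
        assert -1 <= report.silhouette_celltype <= 1
        assert int(report.confusion.to_numpy().sum()) == tp.n_cells
        assert report.n_target_cells == tp.n_cells

    def test_evaluate_without_truth_warns_and_omits_accuracy(
        self, fitted, tiny_hvg_pair, tiny_unlabeled_target
    ):
        sp, _, _ = tiny_hvg_pair
        with pytest.warns(UserWarning, match="truth"):
            report = evaluate_run(fitted, sp, tiny_unlabeled_target)
        assert report.mean_accuracy is None
        assert report.confusion is None
        assert np.isfinite(report.silhouette_celltype)

    def test_save_load_round_trip(self, fitted, tiny_unlabeled_target, tmp_path):
        path = tmp_path / "model.npz"
        fitted.save(path)
        loaded = CellTypeTransferResults.load(path)
        p1, e1 = fitted.annotate(tiny_unlabeled_target)
        p2, e2 = loaded.annotate(tiny_unlabeled_target)
        pd.testing.assert_frame_equal(p1, p2)
        np.testing.assert_array_equal(e1, e2)

    def test_summary_mentions_key_facts(self, fitted):
        text = fitted.summary()
        assert "cell types" in text
        assert "total" in text


def test_supervised_reduction_equals_all_ablations(
    tiny_hvg_pair, tiny_unlabeled_target
):
    """With every auxiliary term ablated the trainer reduces to plain
    supervised cross-entropy on the source."""
    sp, _, _ = tiny_hvg_pair
    res = train(
        sp,
        tiny_unlabeled_target,
        model_spec=small_spec(sp.n_genes),
        cfg=quick_config(
            ablation=frozenset({"no_mse", "no_da", "no_tri", "no_con", "no_vat"})
        ),
    )
    last = res.history.iloc[-1]
    assert last["total"] == pytest.approx(last["ce"], rel=1e-6)
    for term in ("da", "mse", "tri", "con", "vat"):
        assert last[term] == 0.0
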