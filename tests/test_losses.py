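"""Every loss term against an independent naive-loop oracle, plus the
closed-form spot checks and the mining brute force."""

import math

import numpy as np
import pytest

from scrdan import losses as L
from scrdan import nn
from scrdan.losses import LossWeights, TripletIndices
from scrdan.network import ModelSpec, Network


# ---------------------------------------------------------------------------
# loop oracles (deliberately naive, element-by-element)
# ---------------------------------------------------------------------------


def oracle_reconstruction(Xs, Xs_rec, Xt, Xt_rec):
    total = 0.0
    for X, R in ((Xs, Xs_rec), (Xt, Xt_rec)):
        acc = 0.0
        for i in range(X.shape[0]):
            for j in range(X.shape[1]):
                acc += (X[i, j] - R[i, j]) ** 2
        total += acc / X.shape[0]
    return total


def oracle_label(probs, labels):
    acc = 0.0
    for i, lab in enumerate(labels):
        acc -= math.log(max(probs[i, lab], 1e-12))
    return acc / len(labels)


def oracle_domain(d_s, d_t):
    a = sum(math.log(max(d, 1e-12)) for d in d_s) / len(d_s)
    b = sum(math.log(max(1 - d, 1e-12)) for d in d_t) / len(d_t)
    return -a - b


def oracle_mine(Z, labels):
    triplets = []
    n = len(labels)
    for i in range(n):
        best_p, best_pd = None, -1.0
        best_n, best_nd = None, float("inf")
        for j in range(n):
            d = float(np.sum((Z[i].astype(np.float64) - Z[j].astype(np.float64)) ** 2))
            if j != i and labels[j] == labels[i] and d > best_pd:
                best_p, best_pd = j, d
            if labels[j] != labels[i] and d < best_nd:
                best_n, best_nd = j, d
        if best_p is not None and best_n is not None:
            triplets.append((i, best_p, best_n))
    return triplets


def oracle_triplet(Z, triplets, alpha):
    vals = []
    for a, p, n in zip(triplets.anchor, triplets.positive, triplets.negative):
        dp = float(np.sum((Z[a] - Z[p]) ** 2))
        dn = float(np.sum((Z[a] - Z[n]) ** 2))
        vals.append(max(dp - dn + alpha, 0.0))
    return float(np.mean(vals)) if vals else 0.0


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------


class TestReconstruction:
    def test_perfect_reconstruction_is_zero(self, rng):
        X = rng.random((4, 5))
        assert float(L.reconstruction_loss(X, nn.Tensor(X), X, nn.Tensor(X)).data) == 0.0

    def test_hand_example_two_domains(self):
        # one cell per domain, residuals (1,1) and (2,0) -> 2 + 4 = 6
        Xs, Rs = np.array([[1.0, 2.0]]), np.array([[0.0, 1.0]])
        Xt, Rt = np.array([[3.0, 3.0]]), np.array([[1.0, 3.0]])
        out = L.reconstruction_loss(Xs, nn.Tensor(Rs), Xt, nn.Tensor(Rt))
        assert float(out.data) == pytest.approx(6.0)

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            Xs, Rs = rng.random((10, 5)), rng.random((10, 5))
            Xt, Rt = rng.random((7, 5)), rng.random((7, 5))
            out = float(L.reconstruction_loss(Xs, nn.Tensor(Rs), Xt, nn.Tensor(Rt)).data)
            assert out == pytest.approx(
                oracle_reconstruction(Xs, Rs, Xt, Rt), rel=1e-5
            )

    def test_shape_mismatch_rejected(self, rng):
        X = rng.random((3, 4))
        with pytest.raises(ValueError):
            L.reconstruction_loss(X, nn.Tensor(X[:2]), X, nn.Tensor(X))


class TestLabelLoss:
    def test_perfect_onehot_is_zero(self):
        probs = np.eye(3)[[0, 1, 2, 1]]
        assert float(L.label_loss(probs, [0, 1, 2, 1]).data) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_four_classes_is_ln4(self):
        probs = np.full((6, 4), 0.25)
        assert float(L.label_loss(probs, [0, 1, 2, 3, 0, 1]).data) == pytest.approx(
            math.log(4), rel=1e-6
        )

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            raw = rng.random((20, 3)) + 1e-3
            probs = raw / raw.sum(axis=1, keepdims=True)
            labels = rng.integers(0, 3, size=20)
            out = float(L.label_loss(probs, labels).data)
            assert out == pytest.approx(oracle_label(probs, labels), rel=1e-5)

    def test_zero_probability_clamped(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = float(L.label_loss(probs, [1, 0]).data)
        assert np.isfinite(out) and out == pytest.approx(-math.log(1e-12), rel=1e-3)


class TestDomainLoss:
    def test_perfect_discrimination_near_zero(self):
        eps = 1e-7
        out = L.domain_loss(np.full(5, 1 - eps), np.full(5, eps))
        assert float(out.data) == pytest.approx(0.0, abs=1e-5)

    def test_all_half_is_two_ln_two(self):
        out = L.domain_loss(np.full(4, 0.5), np.full(9, 0.5))
        assert float(out.data) == pytest.approx(2 * math.log(2), rel=1e-6)

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            ds = rng.uniform(0.01, 0.99, size=8)
            dt = rng.uniform(0.01, 0.99, size=5)
            assert float(L.domain_loss(ds, dt).data) == pytest.approx(
                oracle_domain(ds, dt), rel=1e-5
            )


class TestTripletMining:
    def test_hand_geometry_one_dimensional(self):
        Z = np.array([[0.0], [1.0], [5.0]])
        tri = L.mine_triplets(Z, np.array(["a", "a", "b"]))
        # anchor 0: positive 1 (only peer), negative 2
        row = list(zip(tri.anchor, tri.positive, tri.negative))
        assert (0, 1, 2) in row and (1, 0, 2) in row
        assert len(tri) == 2  # cell 2 has no same-class peer

    def test_agrees_with_brute_force_on_random_batches(self, rng):
        for _ in range(50):
            Z = rng.normal(size=(30, 8)).astype(np.float32)
            labels = rng.integers(0, 5, size=30)
            tri = L.mine_triplets(Z, labels)
            expected = oracle_mine(Z, labels)
            got = list(zip(tri.anchor, tri.positive, tri.negative))
            assert got == expected

    def test_single_class_yields_empty(self, rng):
        Z = rng.normal(size=(6, 3))
        tri = L.mine_triplets(Z, np.zeros(6, dtype=int))
        assert len(tri) == 0
        assert float(L.triplet_loss(nn.Tensor(Z), tri).data) == 0.0


class TestTripletLoss:
    def test_satisfied_margin_is_zero(self):
        Z = np.array([[0.0], [0.0], [5.0]])
        tri = TripletIndices(np.array([0]), np.array([1]), np.array([2]))
        assert float(L.triplet_loss(nn.Tensor(Z), tri, alpha=1.0).data) == 0.0

    def test_hand_evaluation(self):
        Z = np.array([[0.0], [2.0], [1.0]])
        tri = TripletIndices(np.array([0]), np.array([1]), np.array([2]))
        # [4 - 1 + 1]_+ = 4
        assert float(L.triplet_loss(nn.Tensor(Z), tri, alpha=1.0).data) == pytest.approx(4.0)

    def test_matches_loop_oracle_and_nonnegative(self, rng):
        for _ in range(20):
            Z = rng.normal(size=(15, 4)).astype(np.float32)
            labels = rng.integers(0, 3, size=15)
            tri = L.mine_triplets(Z, labels)
            out = float(L.triplet_loss(nn.Tensor(Z), tri, alpha=0.7).data)
            assert out >= 0
            assert out == pytest.approx(
                oracle_triplet(Z.astype(np.float64), tri, 0.7), rel=1e-4
            )


class TestConsistencyLoss:
    def test_keep_all_masks_give_zero(self, small_network, rng):
        X = rng.random((5, 20)).astype(np.float32)
        ones = np.ones_like(X)
        out = L.consistency_loss_from_masks(small_network, X, ones, ones)
        assert float(out.data) == pytest.approx(0.0, abs=1e-8)

    def test_matches_loop_oracle_with_injected_masks(self, small_network, rng):
        X = rng.random((6, 20)).astype(np.float32)
        m1, m2 = L.consistency_masks(X.shape, 0.3, rng)
        out = float(L.consistency_loss_from_masks(small_network, X, m1, m2).data)

        # oracle: encode each matrix in the same stacked forward, then loop
        stacked = nn.concat_rows(
            [nn.Tensor(X), nn.Tensor(X * m1), nn.Tensor(X * m2)]
        )
        z_all = small_network.encode(stacked, train=True).data
        z, z1, z2 = z_all[:6], z_all[6:12], z_all[12:]
        acc = 0.0
        for i in range(6):
            acc += float(np.sum((z[i] - z1[i]) ** 2) + np.sum((z[i] - z2[i]) ** 2))
        assert out == pytest.approx(acc / 6, rel=1e-4)

    def test_nonnegative_and_seeded(self, small_network):
        X = np.random.default_rng(0).random((8, 20)).astype(np.float32)
        a = float(L.consistency_loss(small_network, X, 0.2, np.random.default_rng(5)).data)
        b = float(L.consistency_loss(small_network, X, 0.2, np.random.default_rng(5)).data)
        assert a >= 0 and a == b

    def test_invalid_fraction_rejected(self, small_network, rng):
        with pytest.raises(ValueError):
            L.consistency_loss(small_network, rng.random((2, 20)), 0.0, rng)


class TestVatLoss:
    def test_zero_epsilon_gives_zero(self, small_network, rng):
        X = rng.random((5, 20)).astype(np.float32)
        out = L.vat_loss(small_network, X, epsilon=0.0, n_candidates=3, rng=rng)
        assert float(out.data) == pytest.approx(0.0, abs=1e-7)

    def test_kl_nonnegative(self, small_network, rng):
        X = rng.random((5, 20)).astype(np.float32)
        out = L.vat_loss(small_network, X, epsilon=2.0, n_candidates=4, rng=rng)
        assert float(out.data) >= -1e-7

    def test_max_selection_at_least_mean_candidate(self, small_network):
        X = np.random.default_rng(2).random((6, 20)).astype(np.float32)
        # same candidate stream: 5-candidate max >= each single random draw's mean
        kls = []
        for seed in range(5):
            one = L.vat_loss(
                small_network, X, epsilon=2.0, n_candidates=1,
                rng=np.random.default_rng(100 + seed),
            )
            kls.append(float(one.data))
        best = L.vat_loss(
            small_network, X, epsilon=2.0, n_candidates=50,
            rng=np.random.default_rng(7),
        )
        assert float(best.data) >= np.mean(kls) - 1e-6


class TestTotalLoss:
    def test_weighted_sum_hand_evaluation(self):
        comps = {k: 1.0 for k in L.COMPONENT_NAMES}
        total, bd = L.total_loss(comps, LossWeights())
        # 1 + 2*1 + 1 (DDANN) + 1 (tri) + 1 + 1*1 (CV) = 7
        assert float(total.data) == pytest.approx(7.0)
        assert bd["total"] == pytest.approx(7.0)

    def test_missing_components_count_as_zero(self):
        total, bd = L.total_loss({"ce": 2.0}, LossWeights())
        assert float(total.data) == pytest.approx(2.0)
        assert bd["da"] == 0.0

    def test_breakdown_reconstructs_total(self, rng):
        w = LossWeights(lambda_da=1.5, lambda_mse=0.5, lambda_vat=2.0)
        comps = {k: float(rng.random()) for k in L.COMPONENT_NAMES}
        total, bd = L.total_loss(comps, w)
        manual = (
            bd["ce"] + w.lambda_da * bd["da"] + w.lambda_mse * bd["mse"]
            + bd["tri"] + bd["con"] + w.lambda_vat * bd["vat"]
        )
        assert float(total.data) == pytest.approx(manual, rel=1e-6)

    def test_nan_component_aborts_with_name(self):
        with pytest.raises(FloatingPointError, match="tri"):
            L.total_loss({"ce": 1.0, "tri": float("nan")}, LossWeights())


class TestLossWeightValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lambda_da": -0.1},
            {"margin_alpha": 0.0},
            {"consistency_dropout_p": 1.0},
            {"vat_candidates": 0},
        ],
    )
    def test_invalid_weights_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LossWeights(**kwargs)
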