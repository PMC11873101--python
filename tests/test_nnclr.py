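"""NNCLR loss, embedding queue and SSL training loop."""

import math

import numpy as np
import pytest

from sliceclr import (ContrastiveBatch, EmbeddingQueue, SSLConfig, batch_loss,
                      cosine_similarity, nearest_neighbor, nnclr_pair_loss,
                      train_ssl)
from sliceclr.backbone import TEST_TINY, ConvNeXtBackbone
from sliceclr.nnclr import _loss_core
from sliceclr._autodiff import Tensor


def brute_force_pair_loss(i, j, z, queue_vectors, tau):
    """Double-loop reference: normalize, scan the queue, sum the softmax."""
    zn = z / np.linalg.norm(z, axis=1, keepdims=True)
    qn = queue_vectors / np.linalg.norm(queue_vectors, axis=1, keepdims=True)
    dists = [np.linalg.norm(zn[i] - q) for q in qn]
    nn = qn[int(np.argmin(dists))]

    def cos(a, b):
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

    num = math.exp(cos(nn, zn[j]) / tau)
    den = sum(math.exp(cos(nn, zn[k]) / tau)
              for k in range(len(z)) if k != i)
    return -math.log(num / den)


class TestCosineSimilarity:
    @pytest.mark.parametrize("a,b,expected", [
        ((1, 0), (0, 1), 0.0),
        ((1, 2), (2, 4), 1.0),
        ((1, 0), (-1, 0), -1.0),
    ])
    def test_reference_pairs(self, a, b, expected):
        assert cosine_similarity(np.array(a, float),
                                 np.array(b, float)) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))


class TestNearestNeighbor:
    def test_picks_closest_entry(self):
        Q = EmbeddingQueue(10).push(np.array([[1.0, 0.0], [0.0, 1.0]]))
        np.testing.assert_allclose(
            nearest_neighbor(np.array([0.9, 0.1]), Q), [1.0, 0.0])

    def test_member_maps_to_itself(self):
        Q = EmbeddingQueue(10).push(np.array([[3.0, 4.0], [0.0, 1.0]]))
        np.testing.assert_allclose(
            nearest_neighbor(np.array([0.6, 0.8]), Q), [0.6, 0.8])

    def test_matches_linear_scan_oracle(self, rng):
        vecs = rng.normal(size=(100, 5))
        Q = EmbeddingQueue(200).push(vecs)
        for _ in range(20):
            z = rng.normal(size=5)
            z /= np.linalg.norm(z)
            dists = np.linalg.norm(Q.vectors - z, axis=1)
            np.testing.assert_allclose(nearest_neighbor(z, Q),
                                       Q.vectors[dists.argmin()])

    def test_empty_queue_is_an_error(self):
        with pytest.raises(RuntimeError):
            nearest_neighbor(np.ones(3), EmbeddingQueue(4))


class TestQueue:
    def test_fifo_eviction(self):
        Q = EmbeddingQueue(3)
        vecs = np.eye(4)
        for v in vecs:
            Q.push(v)
        assert len(Q) == 3
        np.testing.assert_allclose(Q.vectors, np.eye(4)[1:])

    def test_order_preserved_on_partial_fill(self):
        Q = EmbeddingQueue(5).push(np.array([[2.0, 0.0], [0.0, 3.0]]))
        assert len(Q) == 2
        np.testing.assert_allclose(Q.vectors, [[1, 0], [0, 1]])

    def test_replay_oracle(self, rng):
        """Queue contents equal the trailing `capacity` pushes, in order."""
        Q = EmbeddingQueue(7)
        pushed = []
        for _ in range(30):
            chunk = rng.normal(size=(rng.integers(1, 4), 3))
            Q.push(chunk)
            pushed.extend(chunk / np.linalg.norm(chunk, axis=1, keepdims=True))
        np.testing.assert_allclose(Q.vectors, np.array(pushed)[-7:], atol=1e-12)

    def test_entries_stay_unit_norm(self, rng):
        Q = EmbeddingQueue(50).push(rng.normal(size=(20, 6)) * 13)
        np.testing.assert_allclose(np.linalg.norm(Q.vectors, axis=1), 1.0,
                                   atol=1e-5)


class TestPairLoss:
    def test_single_pair_loss_is_zero(self, rng):
        Q = EmbeddingQueue(8).push(rng.normal(size=(4, 3)))
        batch = ContrastiveBatch(rng.normal(size=(2, 3)), temperature=0.37)
        assert nnclr_pair_loss(0, 1, batch, Q) == pytest.approx(0.0, abs=1e-12)
        assert batch_loss(batch, Q) == pytest.approx(0.0, abs=1e-12)

    def test_infinite_temperature_limit_is_uniform_softmax(self, rng):
        """tau -> inf flattens the softmax to 1/(2N-1)."""
        Q = EmbeddingQueue(8).push(rng.normal(size=(4, 3)))
        batch = ContrastiveBatch(rng.normal(size=(4, 3)), temperature=1e6)
        assert batch_loss(batch, Q) == pytest.approx(math.log(3), abs=1e-5)

    def test_vectorized_loss_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(100):
            n_pairs = int(rng.integers(1, 7))   # up to 12 views
            d = int(rng.integers(2, 6))
            z = rng.normal(size=(2 * n_pairs, d))
            qv = rng.normal(size=(int(rng.integers(1, 9)), d))
            tau = float(rng.uniform(0.05, 1.0))
            Q = EmbeddingQueue(64).push(qv)
            batch = ContrastiveBatch(z, temperature=tau)
            directed = []
            for k in range(n_pairs):
                for (i, j) in ((2 * k, 2 * k + 1), (2 * k + 1, 2 * k)):
                    ref = brute_force_pair_loss(i, j, z, qv, tau)
                    worst = max(worst, abs(nnclr_pair_loss(i, j, batch, Q) - ref))
                    directed.append(ref)
            worst = max(worst, abs(batch_loss(batch, Q) - np.mean(directed)))
        assert worst < 1e-6

    def test_loss_bound(self, rng):
        """0 <= loss <= log(2N-1) + 2/tau for cosines in [-1, 1]."""
        for _ in range(50):
            n_pairs = int(rng.integers(1, 5))
            tau = float(rng.uniform(0.05, 2.0))
            z = rng.normal(size=(2 * n_pairs, 4))
            Q = EmbeddingQueue(32).push(rng.normal(size=(6, 4)))
            val = batch_loss(ContrastiveBatch(z, temperature=tau), Q)
            assert -1e-9 <= val <= math.log(max(2 * n_pairs - 1, 1)) + 2 / tau + 1e-9

    def test_swapping_views_within_pairs_preserves_batch_loss(self, rng):
        z = rng.normal(size=(8, 5))
        Q = EmbeddingQueue(16).push(rng.normal(size=(5, 5)))
        swapped = z.reshape(4, 2, 5)[:, ::-1, :].reshape(8, 5)
        a = batch_loss(ContrastiveBatch(z, 0.2), Q)
        b = batch_loss(ContrastiveBatch(swapped, 0.2), Q)
        assert a == pytest.approx(b, abs=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        z0 = rng.normal(size=(6, 3))
        nn = rng.normal(size=(6, 3))
        nn /= np.linalg.norm(nn, axis=1, keepdims=True)
        z = Tensor(z0.copy(), requires_grad=True)
        from sliceclr import _autodiff as ad
        loss = _loss_core(ad.l2_normalize_rows(z), nn, 0.1)
        loss.backward()
        analytic = z.grad.copy()
        eps = 1e-6
        flat = z.data.ravel()
        for i in range(flat.size):
            old = flat[i]
            flat[i] = old + eps
            lp = _loss_core(ad.l2_normalize_rows(Tensor(z.data)), nn, 0.1).item()
            flat[i] = old - eps
            lm = _loss_core(ad.l2_normalize_rows(Tensor(z.data)), nn, 0.1).item()
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            assert abs(num - analytic.ravel()[i]) < 1e-4

    def test_invalid_temperature_rejected(self, rng):
        with pytest.raises(ValueError):
            ContrastiveBatch(rng.normal(size=(4, 3)), temperature=0.0)


class TestTrainSSL:
    def test_short_run_produces_finite_decreasing_trace(self, cohort_slices):
        bb = ConvNeXtBackbone(TEST_TINY, seed=3)
        cfg = SSLConfig(epochs=3, batch_size=16, seed=3)
        _, _, trace = train_ssl(bb, cohort_slices[:64], cfg)
        assert np.isfinite(trace["loss"]).all()
        assert trace["loss"].iloc[-1] < trace["loss"].iloc[0]

    def test_fixed_seed_reproduces_loss_trace_bitwise(self, cohort_slices):
        def run():
            bb = ConvNeXtBackbone(TEST_TINY, seed=5)
            cfg = SSLConfig(epochs=2, batch_size=16, seed=5)
            return train_ssl(bb, cohort_slices[:48], cfg)[2]

        t1, t2 = run(), run()
        assert (t1["loss"].to_numpy() == t2["loss"].to_numpy()).all()

    def test_queue_respects_capacity_during_training(self, cohort_slices):
        bb = ConvNeXtBackbone(TEST_TINY, seed=1)
        cfg = SSLConfig(epochs=1, batch_size=8, queue_size=12, seed=1)
        train_ssl(bb, cohort_slices[:32], cfg)  # would raise internally if broken

    def test_pretraining_tightens_within_class_similarity(self, recovery_run):
        """On held-out strong-effect phantoms, embeddings of same-class
        scans are more cosine-similar than cross-class embeddings."""
        from sliceclr import extract_features, prepare_slices
        slices = []
        for v in recovery_run["test_volumes"]:
            slices.extend(prepare_slices(v, recovery_run["n_keep"]))
        df = extract_features(recovery_run["extractor"], slices)
        X = df[recovery_run["fcols"]].to_numpy()
        y = np.array([recovery_run["classes"].index(l) for l in df["label"]])
        Z = X / np.linalg.norm(X, axis=1, keepdims=True)
        S = Z @ Z.T
        within = (S[np.ix_(y == 0, y == 0)].mean()
                  + S[np.ix_(y == 1, y == 1)].mean()) / 2
        between = S[np.ix_(y == 0, y == 1)].mean()
        assert within > between
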