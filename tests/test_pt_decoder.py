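"""Point hierarchy construction and the Point Transformer decoder."""

import numpy as np
import pytest

from ptgmm.autodiff import Linear, Tensor
from ptgmm.gmm_core import GaussianMixtureModel
from ptgmm.pt_decoder import (DecoderConfig, DecoderOutput,
                              PointTransformerDecoder, PtBlock, apply_deltas,
                              build_hierarchy, transition_up)


def _points(n, seed=0):
    return np.random.default_rng(seed).uniform(-0.4, 0.4, (n, 3))


class TestHierarchy:
    def test_single_level_equals_centers(self):
        pts = _points(30)
        h = build_hierarchy(pts, level_sizes=(30,), k_attn=4)
        assert h.n_levels == 1
        np.testing.assert_array_equal(h.level_points[0], pts)

    def test_default_sizes_on_1024_point_model(self):
        pts = _points(1024)
        h = build_hierarchy(pts, k_attn=8, seed=0)
        assert [len(p) for p in h.level_points] == [64, 256, 1024]

    def test_rejects_oversized_level(self):
        with pytest.raises(ValueError):
            build_hierarchy(_points(50), level_sizes=(80, 100), k_attn=4)

    def test_interpolation_tables_match_bruteforce(self):
        rng = np.random.default_rng(1)
        coarse = rng.uniform(-0.4, 0.4, (40, 3))
        fine = rng.uniform(-0.4, 0.4, (200, 3))
        from ptgmm.pt_decoder import _interp_tables

        idx, w = _interp_tables(fine, coarse)
        for i in range(len(fine)):
            d = np.linalg.norm(coarse - fine[i], axis=1)
            nn = np.argsort(d)[:3]
            assert set(idx[i]) == set(nn)
            invd = 1.0 / d[idx[i]]
            np.testing.assert_allclose(w[i], invd / invd.sum(), rtol=1e-9)

    def test_deterministic_given_seed(self):
        pts = _points(100)
        a = build_hierarchy(pts, (16, None), k_attn=4, seed=5)
        b = build_hierarchy(pts, (16, None), k_attn=4, seed=5)
        np.testing.assert_array_equal(a.level_points[0], b.level_points[0])
        np.testing.assert_array_equal(a.up_idx[0], b.up_idx[0])


class TestPtBlock:
    def test_uniform_attention_when_neighbors_identical(self):
        # all points identical in features and position -> softmax of
        # equal scores -> uniform weights; output = x + sum(attn*(v+d))
        rng = np.random.default_rng(0)
        p, k, c = 6, 3, 8
        pts = np.zeros((p, 3))
        idx = np.tile(np.arange(k), (p, 1))
        block = PtBlock(c, pts, idx, rng)
        x = Tensor(np.ones((1, p, c), np.float32))
        y = block(x)
        # every row identical => output rows identical
        assert np.abs(y.data - y.data[:, :1, :]).max() < 1e-6

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(2)
        p, k, c = 50, 8, 16
        pts = rng.uniform(-0.4, 0.4, (p, 3)).astype(np.float32)
        idx = rng.integers(0, p, (p, k))
        block = PtBlock(c, pts, idx, rng)
        x = rng.normal(size=(2, p, c)).astype(np.float32)
        y = block(Tensor(x)).data

        def lin(layer, v):
            return v @ layer.W.data + layer.b.data

        expected = np.empty_like(x)
        for bi in range(2):
            for i in range(p):
                delta = lin(block.theta2, np.maximum(
                    lin(block.theta1, pts[i] - pts[idx[i]]), 0))
                q = lin(block.phi, x[bi, i])
                kk = lin(block.psi, x[bi, idx[i]])
                v = lin(block.alpha, x[bi, idx[i]])
                scores = lin(block.gamma2, np.maximum(
                    lin(block.gamma1, q[None] - kk + delta), 0))
                e = np.exp(scores - scores.max(axis=0, keepdims=True))
                attn = e / e.sum(axis=0, keepdims=True)
                expected[bi, i] = x[bi, i] + (attn * (v + delta)).sum(axis=0)
        assert np.abs(y - expected).max() < 1e-5

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        p, k, c = 30, 5, 8
        pts = rng.uniform(-0.4, 0.4, (p, 3)).astype(np.float32)
        idx = rng.integers(0, p, (p, k))
        block = PtBlock(c, pts, idx, rng)
        x = rng.normal(size=(1, p, c)).astype(np.float32)
        y = block(Tensor(x)).data

        perm = rng.permutation(p)
        inv = np.argsort(perm)
        block2 = PtBlock(c, pts[perm], inv[idx[perm]], rng)
        # copy weights
        for la, lb in zip(
            (block.phi, block.psi, block.alpha, block.gamma1, block.gamma2,
             block.theta1, block.theta2),
            (block2.phi, block2.psi, block2.alpha, block2.gamma1,
             block2.gamma2, block2.theta1, block2.theta2),
        ):
            lb.W.data = la.W.data.copy()
            lb.b.data = la.b.data.copy()
        y2 = block2(Tensor(x[:, perm])).data
        np.testing.assert_allclose(y2, y[:, perm], atol=1e-5)


class TestTransitionUp:
    def test_partition_of_unity_preserves_constants(self):
        rng = np.random.default_rng(4)
        coarse = rng.uniform(-0.4, 0.4, (10, 3))
        fine = rng.uniform(-0.4, 0.4, (37, 3))
        from ptgmm.pt_decoder import _interp_tables

        idx, w = _interp_tables(fine, coarse)
        feat = Tensor(np.full((2, 10, 6), 3.25, np.float32))
        out = transition_up(feat, idx, w)
        np.testing.assert_allclose(out.data, 3.25, rtol=1e-6)

    def test_coincident_point_takes_full_weight(self):
        coarse = _points(8, seed=5)
        fine = np.concatenate([coarse[2:3], _points(5, seed=6)])
        from ptgmm.pt_decoder import _interp_tables

        idx, w = _interp_tables(fine, coarse)
        assert idx[0, 0] == 2
        np.testing.assert_allclose(w[0], [1.0, 0.0, 0.0], atol=1e-12)

    def test_matches_bruteforce_interpolation(self):
        rng = np.random.default_rng(7)
        coarse = rng.uniform(-0.4, 0.4, (15, 3))
        fine = rng.uniform(-0.4, 0.4, (60, 3))
        from ptgmm.pt_decoder import _interp_tables

        idx, w = _interp_tables(fine, coarse)
        feat = rng.normal(size=(1, 15, 4)).astype(np.float32)
        out = transition_up(Tensor(feat), idx, w).data
        expected = np.zeros((1, 60, 4))
        for i in range(60):
            for j in range(3):
                expected[0, i] += w[i, j] * feat[0, idx[i, j]]
        np.testing.assert_allclose(out, expected, atol=1e-6)


class TestDecoder:
    @pytest.fixture
    def decoder(self):
        pts = _points(120, seed=8)
        h = build_hierarchy(pts, (16, 48, None), k_attn=8, seed=0)
        cfg = DecoderConfig(latent_dim=4, level_sizes=(16, 48, None),
                            channels=(16, 16, 8), resid_channels=4)
        return PointTransformerDecoder(h, cfg, np.random.default_rng(0)), pts

    def test_zero_head_decodes_to_neutral(self, decoder):
        dec, pts = decoder
        out = dec.decode(np.zeros(4))
        assert np.abs(out.d_center).max() == 0.0
        neutral = GaussianMixtureModel(pts, np.ones(len(pts)),
                                       np.full(len(pts), 0.03))
        particle = apply_deltas(neutral, out)
        np.testing.assert_array_equal(particle.centers, neutral.centers)
        np.testing.assert_array_equal(particle.amplitudes,
                                      neutral.amplitudes)

    def test_output_is_five_channels_per_gaussian(self, decoder):
        dec, pts = decoder
        raw = dec.forward_raw(Tensor(np.zeros((3, 4), np.float32)))
        assert raw.shape == (3, len(pts), 5)

    def test_latent_seed_shape_and_zero_case(self, decoder):
        dec, _ = decoder
        z = Tensor(np.zeros((2, 4), np.float32))
        seeded = dec.latent_seed(z)
        assert seeded.shape == (2, 16, 16)

    def test_deterministic_and_continuous_in_latent(self, decoder):
        dec, _ = decoder
        rng = np.random.default_rng(1)
        # give the head nonzero weights so outputs depend on the latent
        dec.head.W.data = rng.normal(
            size=dec.head.W.data.shape).astype(np.float32) * 0.1
        z = rng.normal(size=4).astype(np.float32)
        a = dec.decode(z)
        b = dec.decode(z.copy())
        np.testing.assert_array_equal(a.d_center, b.d_center)
        deltas = []
        for h in (1e-2, 1e-3, 1e-4):
            c = dec.decode(z + np.array([h, 0, 0, 0], np.float32))
            deltas.append(np.abs(c.d_center - a.d_center).max())
        assert deltas[0] > deltas[2]
        assert deltas[2] < 1e-4

    def test_batch_order_invariance(self, decoder):
        dec, _ = decoder
        rng = np.random.default_rng(2)
        dec.head.W.data = rng.normal(
            size=dec.head.W.data.shape).astype(np.float32) * 0.1
        z = rng.normal(size=(4, 4)).astype(np.float32)
        out = dec.forward_raw(Tensor(z)).data
        out_rev = dec.forward_raw(Tensor(z[::-1].copy())).data
        np.testing.assert_allclose(out_rev, out[::-1], atol=1e-6)


class TestApplyDeltas:
    def test_zero_delta_is_identity(self, small_gmm):
        n = small_gmm.n_gaussians
        out = DecoderOutput(np.zeros((n, 3)), np.zeros(n), np.zeros(n))
        g = apply_deltas(small_gmm, out)
        np.testing.assert_array_equal(g.centers, small_gmm.centers)
        np.testing.assert_allclose(g.amplitudes, small_gmm.amplitudes)
        np.testing.assert_allclose(g.widths, small_gmm.widths)

    def test_gate_floor_gives_zero_amplitude(self, small_gmm):
        n = small_gmm.n_gaussians
        out = DecoderOutput(np.zeros((n, 3)), np.full(n, -40.0),
                            np.zeros(n))
        g = apply_deltas(small_gmm, out)
        assert np.abs(g.amplitudes).max() < 1e-12

    def test_centers_shift_additively(self, small_gmm):
        rng = np.random.default_rng(3)
        n = small_gmm.n_gaussians
        dc = rng.uniform(-0.05, 0.05, (n, 3))
        out = DecoderOutput(dc, rng.normal(size=n), rng.normal(size=n))
        g = apply_deltas(small_gmm, out)
        np.testing.assert_allclose(g.centers - small_gmm.centers, dc)

    def test_shape_mismatch_rejected(self, small_gmm):
        out = DecoderOutput(np.zeros((3, 3)), np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError):
            apply_deltas(small_gmm, out)
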