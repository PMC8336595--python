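import math

import numpy as np
import pytest

import reference
from circnet import (
    FeatConfig,
    ModelConfig,
    ModelParams,
    SimConfig,
    build_batch,
    cross_attention,
    encode_junctions,
    forward,
    init_params,
    load_checkpoint,
    loss,
    save_checkpoint,
    simulate_dataset,
    site_attention,
)


def zeroed_gru_params(params: ModelParams) -> ModelParams:
    out = params.copy()
    for name in out.names():
        if name.startswith("gru_"):
            out.arrays[name][:] = 0.0
    return out


class TestEncodeJunctions:
    def test_zero_weights_degenerate(self, tiny_model_config, tiny_params):
        params = zeroed_gru_params(tiny_params)
        ids = np.array([[0, 1, 2, 3], [3, 2, 1, 0]])
        W, alpha = encode_junctions(ids, "acceptor", params, tiny_model_config)
        assert np.allclose(W, 0.0)
        assert np.allclose(alpha, 0.25)

    def test_single_position_softmax(self):
        cfg = ModelConfig(K=2, l=3, L=1, h=4, a_dim=2, f_dim=3, seed=9)
        params = init_params(cfg)
        _, alpha = encode_junctions(np.array([[7]]), "donor", params, cfg)
        assert np.allclose(alpha, 1.0)

    def test_matches_scalar_oracle(self, tiny_model_config, tiny_params, rng):
        for _ in range(5):
            ids = rng.integers(0, tiny_model_config.vocab_size, size=(3, 4))
            W, alpha = encode_junctions(ids, "acceptor", tiny_params, tiny_model_config)
            for row in range(3):
                w_ref, a_ref = reference.encode_site(
                    tiny_params.arrays, "a", ids[row].tolist(), tiny_model_config.h
                )
                np.testing.assert_allclose(W[row], w_ref, atol=1e-5)
                np.testing.assert_allclose(alpha[row], a_ref, atol=1e-5)

    def test_sides_use_disjoint_parameters(self, tiny_model_config, tiny_params):
        ids = np.array([[1, 2, 3, 4]])
        W_a, _ = encode_junctions(ids, "acceptor", tiny_params, tiny_model_config)
        W_d, _ = encode_junctions(ids, "donor", tiny_params, tiny_model_config)
        assert not np.allclose(W_a, W_d)

    def test_bad_side(self, tiny_model_config, tiny_params):
        with pytest.raises(ValueError):
            encode_junctions(np.zeros((1, 4), dtype=int), "both", tiny_params, tiny_model_config)


class TestCrossAttention:
    def test_single_pair_swaps_embeddings(self):
        w_a = np.array([[1.0, 2.0]])
        w_d = np.array([[3.0, 4.0]])
        V_a, V_d, beta_a, beta_d = cross_attention(w_a, w_d)
        assert np.allclose(beta_a, [[1.0]]) and np.allclose(beta_d, [[1.0]])
        assert np.allclose(V_a, w_d) and np.allclose(V_d, w_a)

    def test_two_donor_softmax_values(self):
        # logits are 1 and 0 -> weights e/(e+1), 1/(e+1)
        w_a = np.array([[1.0, 0.0]])
        w_d = np.array([[1.0, 0.0], [0.0, 1.0]])
        V_a, _, beta_a, _ = cross_attention(w_a, w_d)
        e = math.e
        np.testing.assert_allclose(beta_a[0], [e / (e + 1), 1 / (e + 1)], atol=1e-6)
        np.testing.assert_allclose(V_a[0], [e / (e + 1), 1 / (e + 1)], atol=1e-6)

    def test_identical_donors_split_evenly(self):
        w_a = np.array([[0.3, -0.7]])
        w_d = np.array([[1.0, 2.0], [1.0, 2.0]])
        _, _, beta_a, _ = cross_attention(w_a, w_d)
        np.testing.assert_allclose(beta_a[0], [0.5, 0.5])

    def test_matches_scalar_oracle(self, rng):
        W_a = rng.normal(size=(3, 4))
        W_d = rng.normal(size=(2, 4))
        V_a, V_d, beta_a, beta_d = cross_attention(W_a, W_d)
        rV_a, rV_d, rb_a, rb_d = reference.cross_attention(W_a.tolist(), W_d.tolist())
        np.testing.assert_allclose(V_a, rV_a, atol=1e-6)
        np.testing.assert_allclose(V_d, rV_d, atol=1e-6)
        np.testing.assert_allclose(beta_a, rb_a, atol=1e-6)
        np.testing.assert_allclose(beta_d, rb_d, atol=1e-6)

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            cross_attention(np.ones((2, 3)), np.ones((2, 3)), mask=np.zeros(2))


class TestSiteAttention:
    def test_single_site_identity(self, tiny_model_config, tiny_params, rng):
        v = rng.normal(size=(1, 2 * tiny_model_config.h))
        r, gamma = site_attention(v, "acceptor", tiny_params, tiny_model_config)
        np.testing.assert_allclose(gamma, [1.0])
        np.testing.assert_allclose(r, v[0])

    def test_identical_rows_uniform(self, tiny_model_config, tiny_params):
        v = np.tile(np.arange(2 * tiny_model_config.h, dtype=float), (3, 1))
        _, gamma = site_attention(v, "donor", tiny_params, tiny_model_config)
        np.testing.assert_allclose(gamma, [1 / 3] * 3)

    def test_matches_scalar_oracle(self, tiny_model_config, tiny_params, rng):
        v = rng.normal(size=(4, 2 * tiny_model_config.h))
        r, gamma = site_attention(v, "acceptor", tiny_params, tiny_model_config)
        r_ref, g_ref = reference.site_attention(tiny_params.arrays, "a", v.tolist())
        np.testing.assert_allclose(r, r_ref, atol=1e-5)
        np.testing.assert_allclose(gamma, g_ref, atol=1e-5)

    def test_all_masked_rejected(self, tiny_model_config, tiny_params):
        with pytest.raises(ValueError):
            site_attention(np.ones((2, 8)), "donor", tiny_params, tiny_model_config,
                           mask=np.zeros(2))


def _batch_for(cfg, n_genes=6, seed=3, exon_range=(1, 3)):
    ds = simulate_dataset(SimConfig(n_genes=n_genes, exon_count_range=exon_range, seed=seed))
    return ds, build_batch(ds.records, FeatConfig(L=cfg.L, K=cfg.K))


class TestForward:
    def test_scores_strictly_inside_unit_interval(self, tiny_model_config, tiny_params):
        _, batch = _batch_for(tiny_model_config)
        res = forward(batch, tiny_params, tiny_model_config)
        assert np.all(res.scores > 0.0) and np.all(res.scores < 1.0)

    def test_zero_head_gives_half(self, tiny_model_config, tiny_params):
        params = tiny_params.copy()
        params.arrays["Fp_W"][:] = 0.0
        params.arrays["Fp_b"][:] = 0.0
        _, batch = _batch_for(tiny_model_config)
        res = forward(batch, params, tiny_model_config)
        np.testing.assert_allclose(res.scores, 0.5)

    def test_duplicate_record_identical_scores(self, tiny_model_config, tiny_params):
        ds, _ = _batch_for(tiny_model_config, n_genes=2)
        batch = build_batch([ds.records[0], ds.records[0]],
                            FeatConfig(L=tiny_model_config.L, K=tiny_model_config.K))
        res = forward(batch, tiny_params, tiny_model_config)
        assert res.scores[0] == res.scores[1]

    def test_attention_rows_normalized(self, tiny_model_config, tiny_params):
        _, batch = _batch_for(tiny_model_config, n_genes=8, exon_range=(1, 4))
        res = forward(batch, tiny_params, tiny_model_config)
        for maps in res.maps:
            np.testing.assert_allclose(maps.alpha_a.sum(axis=1), 1.0, atol=1e-6)
            np.testing.assert_allclose(maps.alpha_d.sum(axis=1), 1.0, atol=1e-6)
            np.testing.assert_allclose(maps.beta_a.sum(axis=1), 1.0, atol=1e-6)
            np.testing.assert_allclose(maps.beta_d.sum(axis=1), 1.0, atol=1e-6)
            np.testing.assert_allclose(maps.gamma_a.sum(), 1.0, atol=1e-6)
            np.testing.assert_allclose(maps.gamma_d.sum(), 1.0, atol=1e-6)
            assert (maps.beta_a >= 0).all() and (maps.gamma_d >= 0).all()

    def test_mask_invariance_exact(self, tiny_model_config, tiny_params, rng):
        ds, batch = _batch_for(tiny_model_config, n_genes=10, exon_range=(1, 5))
        base = forward(batch, tiny_params, tiny_model_config).scores
        padded = np.where(batch.site_mask == 0)
        assert len(padded[0]) > 0, "need padded sites for this test"
        for _ in range(5):
            mutated_a = batch.acceptor_ids.copy()
            mutated_d = batch.donor_ids.copy()
            mutated_a[padded[0], padded[1]] = rng.integers(0, tiny_model_config.vocab_size,
                                                           size=(len(padded[0]), batch.acceptor_ids.shape[2]))
            mutated_d[padded[0], padded[1]] = rng.integers(0, tiny_model_config.vocab_size,
                                                           size=(len(padded[0]), batch.donor_ids.shape[2]))
            from circnet.features import JunctionBatch
            mutated = JunctionBatch(mutated_a, mutated_d, batch.site_mask, batch.labels)
            assert (forward(mutated, tiny_params, tiny_model_config).scores == base).all()

    def test_full_forward_matches_oracle(self, tiny_model_config, tiny_params):
        ds, batch = _batch_for(tiny_model_config, n_genes=6, exon_range=(1, 3))
        res = forward(batch, tiny_params, tiny_model_config)
        for b, rec in enumerate(ds.records):
            m = rec.n_exons
            ref = reference.forward_record(
                tiny_params, tiny_model_config.h,
                batch.acceptor_ids[b, :m].tolist(), batch.donor_ids[b, :m].tolist(),
            )
            assert abs(ref["y_hat"] - res.scores[b]) < 1e-5
            np.testing.assert_allclose(res.maps[b].beta_d, ref["beta_d"], atol=1e-5)
            np.testing.assert_allclose(res.maps[b].gamma_a, ref["gamma_a"], atol=1e-5)

    def test_site_permutation_equivariance(self, tiny_model_config, tiny_params):
        # permuting exon order permutes beta/gamma consistently and keeps y_hat
        ds, _ = _batch_for(tiny_model_config, n_genes=20, exon_range=(3, 3), seed=6)
        rec = ds.records[0]
        feat = FeatConfig(L=tiny_model_config.L, K=tiny_model_config.K)
        batch = build_batch([rec], feat)
        res = forward(batch, tiny_params, tiny_model_config)
        perm = [2, 0, 1]
        from circnet.features import JunctionBatch
        batch_p = JunctionBatch(batch.acceptor_ids[:, perm], batch.donor_ids[:, perm],
                                batch.site_mask, batch.labels)
        res_p = forward(batch_p, tiny_params, tiny_model_config)
        assert abs(res.scores[0] - res_p.scores[0]) < 1e-12
        np.testing.assert_allclose(res_p.maps[0].gamma_a,
                                   res.maps[0].gamma_a[perm], atol=1e-12)
        np.testing.assert_allclose(res_p.maps[0].beta_d,
                                   res.maps[0].beta_d[np.ix_(perm, perm)], atol=1e-12)


class TestLoss:
    def test_ln2_at_half(self):
        assert abs(loss([0.5], [1]) - math.log(2)) < 1e-9

    def test_perfect_fit_limit(self):
        assert loss([1 - 1e-9, 1e-9], [1, 0]) < 1e-6

    def test_matches_elementwise_oracle(self, tiny_params, rng):
        y_hat = rng.uniform(0.01, 0.99, size=32)
        y = rng.integers(0, 2, size=32)
        ref = reference.bce_loss(y_hat.tolist(), y.tolist(), tiny_params, 1e-3)
        assert abs(loss(y_hat, y, tiny_params, 1e-3) - ref) < 1e-6

    def test_l2_term(self, tiny_params):
        base = loss([0.5], [1])
        with_reg = loss([0.5], [1], tiny_params, 1e-3)
        assert with_reg == pytest.approx(base + 1e-3 * tiny_params.l2_norm_sq())

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            loss([float("nan")], [1])

    def test_nonnegative_finite(self, rng):
        for _ in range(20):
            val = loss(rng.uniform(0, 1, 8), rng.integers(0, 2, 8))
            assert val >= 0 and np.isfinite(val)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, tiny_model_config, tiny_params):
        path = tmp_path / "model.ckpt"
        save_checkpoint(path, tiny_params, tiny_model_config, extra={"seed": 5})
        params, cfg, extra = load_checkpoint(path)
        assert cfg == tiny_model_config
        assert extra["seed"] == 5
        for name in tiny_params.names():
            np.testing.assert_array_equal(params[name], tiny_params[name])
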