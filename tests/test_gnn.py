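"""Graph convolution layer, full forward pass, and the uncertainty loss."""

import numpy as np
import pytest

from nmrshift.featurize import featurize_molecule, normalize_adjacency
from nmrshift.gnn import (
    GraphConvShiftRegressor,
    ModelConfig,
    conv_layer_forward,
    init_params,
    model_forward,
    uncertainty_loss,
    _backward,
    _forward,
)

from conftest import random_adjacency


def brute_force_layer(g_norm, L, W):
    """Per-vertex oracle: out[i] = relu(max_k sum_j G~_k[i,j] W^T l_j).

    Written as the literal neighborhood sum (self-loops included through the
    normalized adjacency), looping over vertices and channels.
    """
    n_chan, m, _ = g_norm.shape
    d_out = W.shape[1]
    out = np.zeros((m, d_out))
    for i in range(m):
        per_channel = np.zeros((n_chan, d_out))
        for k in range(n_chan):
            acc = np.zeros(d_out)
            for j in range(m):
                if g_norm[k, i, j] != 0:
                    acc += g_norm[k, i, j] * (W.T @ L[j])
            per_channel[k] = acc
        out[i] = np.maximum(per_channel.max(axis=0), 0.0)
    return out


class TestConvLayer:
    def test_matrix_form_matches_per_vertex_sum(self):
        """The batched matrix expression equals the literal per-vertex
        neighborhood sum on 200 random small graphs and random weights."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 7))
            m = n + int(rng.integers(0, 2))
            chans, mask = random_adjacency(rng, n, m)
            g_norm = np.stack([normalize_adjacency(chans[k], mask) for k in range(4)])
            d_in, d_out = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            L = rng.normal(size=(m, d_in)) * mask[:, None]
            W = rng.normal(size=(d_in, d_out))
            got = conv_layer_forward(L, g_norm, W, valid_mask=mask, residual=False)
            want = brute_force_layer(g_norm, L, W) * mask[:, None]
            assert np.allclose(got, want, rtol=1e-6, atol=1e-9)

    def test_zero_weights_residual_identity(self):
        rng = np.random.default_rng(1)
        chans, mask = random_adjacency(rng, 4, 4)
        g_norm = np.stack([normalize_adjacency(chans[k], mask) for k in range(4)])
        L = rng.normal(size=(4, 3))
        out = conv_layer_forward(L, g_norm, np.zeros((3, 3)), residual=True)
        assert np.array_equal(out, L)

    def test_isolated_atom_self_loop_only(self):
        """With no bonds, G~ = I on the vertex: output = relu(W^T l_i)."""
        rng = np.random.default_rng(2)
        g_norm = np.zeros((4, 3, 3))
        mask = np.array([1.0, 0, 0])
        for k in range(4):
            g_norm[k] = normalize_adjacency(np.zeros((3, 3)), mask)
        L = np.zeros((3, 5))
        L[0] = rng.normal(size=5)
        W = rng.normal(size=(5, 4))
        out = conv_layer_forward(L, g_norm, W, valid_mask=mask, residual=False)
        assert np.allclose(out[0], np.maximum(W.T @ L[0], 0.0))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="does not match"):
            conv_layer_forward(np.zeros((3, 4)), np.zeros((4, 3, 3)), np.zeros((5, 2)))


@pytest.fixture(scope="module")
def small_config():
    return ModelConfig(n_layers=3, width=12, head_width=8, m_max=16)


class TestModelForward:
    def test_output_contract(self, small_config, ethanol):
        params = init_params(small_config, np.random.default_rng(3))
        L, stack, mask = featurize_molecule(ethanol, m_max=16)
        pred = model_forward(L, stack.g_norm, params, small_config, mask)
        assert pred.mu.shape == (16,) and pred.sigma.shape == (16,)
        assert np.all(pred.sigma[mask.astype(bool)] > 0)

    def test_deterministic_forward(self, small_config, ethanol):
        params = init_params(small_config, np.random.default_rng(4))
        L, stack, mask = featurize_molecule(ethanol, m_max=16)
        a = model_forward(L, stack.g_norm, params, small_config, mask)
        b = model_forward(L, stack.g_norm, params, small_config, mask)
        assert np.array_equal(a.mu, b.mu) and np.array_equal(a.sigma, b.sigma)

    def test_permutation_equivariance_full_forward(self, small_config, small_molecule_set):
        """100 random (graph, permutation) pairs: relabeled input gives
        relabeled mu/sigma, exactly (up to float noise)."""
        rng = np.random.default_rng(5)
        params = init_params(small_config, rng)
        pairs = 0
        while pairs < 100:
            g = small_molecule_set[pairs % len(small_molecule_set)]
            perm = list(rng.permutation(g.n_atoms))
            gp = g.permuted(perm)
            L, stack, mask = featurize_molecule(g, m_max=16)
            Lp, stackp, maskp = featurize_molecule(gp, m_max=16)
            a = model_forward(L, stack.g_norm, params, small_config, mask)
            b = model_forward(Lp, stackp.g_norm, params, small_config, maskp)
            p = np.asarray(perm)
            n = g.n_atoms
            assert np.allclose(b.mu[p], a.mu[:n], rtol=1e-9, atol=1e-9)
            assert np.allclose(b.sigma[p], a.sigma[:n], rtol=1e-9, atol=1e-9)
            pairs += 1

    def test_depth_collapse_with_zero_conv_weights(self, small_config, ethanol):
        """Residual layers with zero weights pass the layer-1 output through."""
        rng = np.random.default_rng(6)
        deep = ModelConfig(n_layers=6, width=12, head_width=8, m_max=16)
        params = init_params(deep, rng)
        shallow_params = {k: v.copy() for k, v in params.items()}
        for layer in range(1, 6):
            params[f"conv_W{layer}"] = np.zeros_like(params[f"conv_W{layer}"])
        L, stack, mask = featurize_molecule(ethanol, m_max=16)
        _, _, cache_deep = _forward(params, deep, L[None], stack.g_norm[None], mask[None], True)
        one = ModelConfig(n_layers=1, width=12, head_width=8, m_max=16)
        one_params = {"conv_W0": shallow_params["conv_W0"]}
        one_params.update({k: v for k, v in shallow_params.items() if not k.startswith("conv")})
        _, _, cache_one = _forward(one_params, one, L[None], stack.g_norm[None], mask[None], True)
        assert np.allclose(cache_deep["emb"], cache_one["emb"])

    def test_gradients_match_finite_differences(self, small_config, small_molecule_set):
        """Analytic backprop agrees with central differences on random params."""
        rng = np.random.default_rng(7)
        cfg = ModelConfig(n_layers=2, width=6, head_width=4, m_max=14, n_residual_blocks=2)
        params = init_params(cfg, rng)
        g = small_molecule_set[0]
        L, stack, mask = featurize_molecule(g, m_max=14)
        y = np.full((1, 14), np.nan)
        y[0, : g.n_atoms : 2] = rng.normal(size=len(range(0, g.n_atoms, 2)))
        obs = np.isfinite(y).astype(float)

        def loss_of(p):
            mu, sig, _ = _forward(p, cfg, L[None], stack.g_norm[None], mask[None])
            return uncertainty_loss(mu, sig, y, obs)

        mu, sig, cache = _forward(params, cfg, L[None], stack.g_norm[None], mask[None], True)
        _, dmu, dsig = uncertainty_loss(mu, sig, y, obs, return_grads=True)
        grads = _backward(params, cfg, stack.g_norm[None], cache, dmu, dsig)
        eps = 1e-6
        for key in ["conv_W0", "conv_W1", "mu_W3", "sg_W2", "mu_res0_W", "sg_b1"]:
            flat = params[key].reshape(-1)
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss_of(params)
                flat[idx] = orig - eps
                lm = loss_of(params)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[key].reshape(-1)[idx]
                assert num == pytest.approx(ana, rel=1e-4, abs=1e-7), key


class TestUncertaintyLoss:
    def test_zero_residual_unit_sigma(self):
        mu = np.array([5.0])
        loss = uncertainty_loss(mu, np.array([1.0]), np.array([5.0]), np.array([1.0]))
        assert loss == pytest.approx(1.0, abs=1e-12)

    def test_residual_two_unit_sigma(self):
        loss = uncertainty_loss(
            np.array([3.0]), np.array([1.0]), np.array([5.0]), np.array([1.0])
        )
        assert loss == pytest.approx(3.0, abs=1e-12)

    def test_stationary_at_sigma_r_two_thirds(self):
        """d/dsigma [(r^2)/(2 sigma^2) + sigma] = 0 at sigma = r^(2/3)."""
        for r in (0.5, 1.0, 2.0, 7.0):
            sstar = r ** (2.0 / 3.0)
            _, _, dsig = uncertainty_loss(
                np.array([0.0]), np.array([sstar]), np.array([r]), np.array([1.0]),
                return_grads=True,
            )
            assert dsig[0] == pytest.approx(0.0, abs=1e-10)
            # and it is a minimum: gradient negative below, positive above
            _, _, lo = uncertainty_loss(
                np.array([0.0]), np.array([0.5 * sstar]), np.array([r]), np.array([1.0]),
                return_grads=True,
            )
            _, _, hi = uncertainty_loss(
                np.array([0.0]), np.array([2.0 * sstar]), np.array([r]), np.array([1.0]),
                return_grads=True,
            )
            assert lo[0] < 0 < hi[0]

    def test_masked_atoms_contribute_nothing(self):
        rng = np.random.default_rng(9)
        y = np.array([1.0, np.nan, 2.0, np.nan])
        obs = np.array([1.0, 0, 1, 0])
        mu = np.array([0.9, 0.0, 2.2, 0.0])
        sig = np.ones(4)
        base = uncertainty_loss(mu, sig, y, obs)
        for _ in range(20):
            mu2, sig2 = mu.copy(), sig.copy()
            mu2[~obs.astype(bool)] = rng.normal(scale=100)
            sig2[~obs.astype(bool)] = abs(rng.normal(scale=100)) + 1e-3
            assert uncertainty_loss(mu2, sig2, y, obs) == pytest.approx(base, abs=1e-12)

    def test_all_unobserved_gives_zero(self):
        assert uncertainty_loss(np.ones(3), np.ones(3), np.full(3, np.nan), np.zeros(3)) == 0.0

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(FloatingPointError):
            uncertainty_loss(np.zeros(1), np.zeros(1), np.zeros(1), np.ones(1))


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path, small_molecule_set):
        from nmrshift.synthetic import SyntheticShiftOracle, assign_shifts, targets_from_assignments

        mols = small_molecule_set[:15]
        oracle = SyntheticShiftOracle()
        assigns = assign_shifts(mols, oracle, seed=1, nuclei=("C13",))
        y = targets_from_assignments(mols, assigns, "C13")
        est = GraphConvShiftRegressor(
            n_layers=2, width=16, head_width=8, m_max=16, epochs=2, seed=0
        )
        est.fit(mols, y)
        path = tmp_path / "model.npz"
        est.save(path)
        loaded = GraphConvShiftRegressor.load(path)
        a = est.predict_dist(mols[:3])
        b = loaded.predict_dist(mols[:3])
        for pa, pb in zip(a, b):
            assert np.allclose(pa.mu, pb.mu) and np.allclose(pa.sigma, pb.sigma)
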