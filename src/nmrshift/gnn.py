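"""Bond-order-aware residual graph convolutional network with uncertainty.

The model predicts, for every atom of a molecule, a chemical shift estimate
``mu`` (ppm) and a per-atom uncertainty ``sigma`` (ppm, strictly positive).

Architecture
------------
Per-vertex features are stacked into an ``M x D`` matrix ``L``.  A layer
computes, with one shared weight matrix ``W`` and the four normalized
bond-order adjacency channels ``G~_k`` (k in {1, 1.5, 2, 3})::

    out = relu( max_k  G~_k @ L @ W )      (elementwise max over channels)
    out = out + L                          (residual, when shapes match)

The first layer (37 -> width) has no residual; conv layers carry no bias, so
padded rows stay exactly zero (they are additionally re-zeroed after every
layer).  The final per-vertex embedding feeds two heads:

* ``sigma``: linear+relu (width -> head), linear (head -> 1), then
  softplus + 1e-4 to enforce positivity;
* ``mu``: linear+relu (width -> head), three residual blocks
  (relu(xW+b) + x), linear+relu (head -> head), final linear (head -> 1).

Training minimizes the heteroscedastic loss, averaged over observed atoms::

    (y - mu)^2 / (2 sigma^2) + sigma

which is stationary at sigma = |y - mu|^(2/3); unobserved atoms contribute
exactly zero.  Everything (forward, hand-derived backward, Adam) is plain
NumPy: at desk scale (4 layers, width 128) a model trains on a CPU in
minutes, and the published scale (10 layers, width 2048) is just a config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .featurize import M_DEFAULT, N_FEATURES, FeaturizedBatch, MolecularGraphFeaturizer
from .graphs import MolecularGraph

SIGMA_EPS = 1e-4  # ppm; floor added after softplus


@dataclass
class ModelConfig:
    """Network shape. Defaults are the published scale; tests shrink it."""

    n_layers: int = 10
    width: int = 2048
    head_width: int = 128
    m_max: int = M_DEFAULT
    n_residual_blocks: int = 3
    n_features: int = N_FEATURES

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"ModelConfig.{name} must be positive, got {v}")


@dataclass
class ShiftPrediction:
    """Per-atom prediction for one molecule (arrays of length n_atoms)."""

    mu: np.ndarray
    sigma: np.ndarray
    valid_mask: np.ndarray


# ----------------------------------------------------------------------
# Parameter initialisation
# ----------------------------------------------------------------------

def init_params(config: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """He-initialised weights; biases zero; conv layers are bias-free."""
    p: dict[str, np.ndarray] = {}

    def he(fan_in, shape):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    d_in = config.n_features
    for layer in range(config.n_layers):
        p[f"conv_W{layer}"] = he(d_in, (d_in, config.width))
        d_in = config.width
    w, h = config.width, config.head_width
    p["mu_W1"], p["mu_b1"] = he(w, (w, h)), np.zeros(h)
    for r in range(config.n_residual_blocks):
        p[f"mu_res{r}_W"], p[f"mu_res{r}_b"] = he(h, (h, h)), np.zeros(h)
    p["mu_W2"], p["mu_b2"] = he(h, (h, h)), np.zeros(h)
    # small output layers: start near mu = 0, sigma = softplus(0.54) ~ 1
    # (in standardized target units), keeping the 1/sigma^2 loss term tame
    p["mu_W3"], p["mu_b3"] = 0.1 * he(h, (h, 1)), np.zeros(1)
    p["sg_W1"], p["sg_b1"] = he(w, (w, h)), np.zeros(h)
    p["sg_W2"], p["sg_b2"] = 0.1 * he(h, (h, 1)), np.full(1, 0.54)
    return p


# ----------------------------------------------------------------------
# Forward pass
# ----------------------------------------------------------------------

def conv_layer_forward(
    L_in: np.ndarray,
    g_norm: np.ndarray,
    W: np.ndarray,
    valid_mask: np.ndarray | None = None,
    residual: bool | None = None,
) -> np.ndarray:
    """One graph convolution on a single molecule.

    Parameters
    ----------
    L_in : (M, D_in) vertex features.
    g_norm : (n_channels, M, M) normalized adjacency channels.
    W : (D_in, D_out) shared channel weights.
    valid_mask : optional (M,) 0/1; output rows beyond it are zeroed.
    residual : add the input back when shapes match. Default: automatic.

    Returns the (M, D_out) output ``relu(max_k G~_k L W) [+ L]``.
    """
    if L_in.shape[1] != W.shape[0]:
        raise ValueError(f"feature dim {L_in.shape[1]} does not match W rows {W.shape[0]}")
    q = g_norm @ (L_in @ W)  # (K, M, D_out)
    out = np.maximum(np.max(q, axis=0), 0.0)
    if residual is None:
        residual = W.shape[0] == W.shape[1]
    if residual:
        if L_in.shape != out.shape:
            raise ValueError("residual connection requires D_in == D_out")
        out = out + L_in
    if valid_mask is not None:
        out = out * valid_mask[:, None]
    return out


def _forward(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    feats: np.ndarray,  # (B, M, F)
    adj: np.ndarray,  # (B, K, M, M)
    mask: np.ndarray,  # (B, M)
    want_cache: bool = False,
):
    """Batched forward pass; returns (mu, sigma, cache)."""
    mask3 = mask[:, :, None]
    L = feats * mask3
    cache: dict = {"conv": []} if want_cache else None

    for layer in range(config.n_layers):
        W = params[f"conv_W{layer}"]
        p_chan = adj @ L[:, None, :, :]  # (B, K, M, D_in)
        q = p_chan @ W  # (B, K, M, D_out)
        kmax = np.argmax(q, axis=1)  # (B, M, D_out)
        z = np.max(q, axis=1)
        pos = z > 0
        a = np.where(pos, z, 0.0)
        res = layer > 0
        out = (a + L if res else a) * mask3
        if want_cache:
            cache["conv"].append(
                {"p": p_chan, "kmax": kmax.astype(np.uint8), "pos": pos, "res": res}
            )
        L = out

    emb = L  # (B, M, width)

    def lin(x, Wn, bn):
        return x @ params[Wn] + params[bn]

    # mu head
    h1_pre = lin(emb, "mu_W1", "mu_b1")
    h1 = np.maximum(h1_pre, 0.0)
    x = h1
    res_pres = []
    for r in range(config.n_residual_blocks):
        pre = lin(x, f"mu_res{r}_W", f"mu_res{r}_b")
        res_pres.append(pre)
        x = np.maximum(pre, 0.0) + x
    h2_pre = lin(x, "mu_W2", "mu_b2")
    h2 = np.maximum(h2_pre, 0.0)
    mu = lin(h2, "mu_W3", "mu_b3")[..., 0]

    # sigma head
    s1_pre = lin(emb, "sg_W1", "sg_b1")
    s1 = np.maximum(s1_pre, 0.0)
    s_raw = lin(s1, "sg_W2", "sg_b2")[..., 0]
    sigma = _softplus(s_raw) + SIGMA_EPS

    if want_cache:
        cache.update(
            emb=emb, h1_pre=h1_pre, h1=h1, res_pres=res_pres, h2_pre=h2_pre, h2=h2,
            s1_pre=s1_pre, s1=s1, s_raw=s_raw, mask=mask,
        )
    return mu, sigma, cache


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _backward(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    adj: np.ndarray,
    cache: dict,
    dmu: np.ndarray,  # (B, M)
    dsigma: np.ndarray,  # (B, M)
) -> dict[str, np.ndarray]:
    """Hand-derived gradients of the forward pass."""
    g: dict[str, np.ndarray] = {}

    def back_lin(x, dy, Wn, bn):
        g[Wn] = g.get(Wn, 0) + np.einsum("bmi,bmo->io", x, dy)
        g[bn] = g.get(bn, 0) + dy.sum(axis=(0, 1))
        return dy @ params[Wn].T

    # sigma head (softplus derivative = logistic)
    ds_raw = dsigma * _sigmoid(cache["s_raw"])
    ds1 = back_lin(cache["s1"], ds_raw[..., None], "sg_W2", "sg_b2")
    ds1_pre = ds1 * (cache["s1_pre"] > 0)
    demb = back_lin(cache["emb"], ds1_pre, "sg_W1", "sg_b1")

    # mu head
    dh2 = back_lin(cache["h2"], dmu[..., None], "mu_W3", "mu_b3")
    dh2_pre = dh2 * (cache["h2_pre"] > 0)
    # recompute residual-chain activations (x_r) from cached pre-activations
    xs = [cache["h1"]]
    for r in range(config.n_residual_blocks):
        xs.append(np.maximum(cache["res_pres"][r], 0.0) + xs[-1])
    dx = back_lin(xs[-1], dh2_pre, "mu_W2", "mu_b2")
    for r in reversed(range(config.n_residual_blocks)):
        dpre = dx * (cache["res_pres"][r] > 0)
        dx = back_lin(xs[r], dpre, f"mu_res{r}_W", f"mu_res{r}_b") + dx
    dh1_pre = dx * (cache["h1_pre"] > 0)
    demb = demb + back_lin(cache["emb"], dh1_pre, "mu_W1", "mu_b1")

    # conv stack
    mask3 = cache["mask"][:, :, None]
    dL = demb * mask3
    n_chan = adj.shape[1]
    chan_idx = np.arange(n_chan, dtype=np.uint8)[None, :, None, None]
    for layer in reversed(range(config.n_layers)):
        c = cache["conv"][layer]
        dout = dL
        da = dout  # residual branch handled below
        dz = da * c["pos"]
        dq = (c["kmax"][:, None, :, :] == chan_idx) * dz[:, None, :, :]
        g[f"conv_W{layer}"] = np.einsum("bkmi,bkmo->io", c["p"], dq)
        dp = dq @ params[f"conv_W{layer}"].T
        dL = np.matmul(adj, dp).sum(axis=1)  # adjacency symmetric
        if c["res"]:
            dL = dL + dout
        dL = dL * mask3
    return g


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ----------------------------------------------------------------------
# Loss
# ----------------------------------------------------------------------

def uncertainty_loss(
    mu: np.ndarray,
    sigma: np.ndarray,
    y: np.ndarray,
    observed_mask: np.ndarray,
    return_grads: bool = False,
):
    """Mean over observed atoms of ``(y - mu)^2 / (2 sigma^2) + sigma``.

    Unobserved atoms (mask 0) contribute exactly zero regardless of their
    predictions.  ``y`` may hold NaN at unobserved positions.
    """
    obs = observed_mask.astype(bool)
    n_obs = int(obs.sum())
    if n_obs == 0:
        if return_grads:
            return 0.0, np.zeros_like(mu), np.zeros_like(sigma)
        return 0.0
    if np.any(sigma[obs] <= 0):
        raise FloatingPointError("sigma must be strictly positive at observed atoms")
    r = np.where(obs, y - mu, 0.0)
    s = np.where(obs, sigma, 1.0)
    loss = float(np.sum(np.where(obs, r**2 / (2.0 * s**2) + s, 0.0)) / n_obs)
    if not return_grads:
        return loss
    dmu = np.where(obs, -r / s**2, 0.0) / n_obs
    dsigma = np.where(obs, 1.0 - r**2 / s**3, 0.0) / n_obs
    return loss, dmu, dsigma


# ----------------------------------------------------------------------
# Single-molecule convenience forward
# ----------------------------------------------------------------------

def model_forward(
    L0: np.ndarray,
    g_norm: np.ndarray,
    params: dict[str, np.ndarray],
    config: ModelConfig,
    valid_mask: np.ndarray | None = None,
) -> ShiftPrediction:
    """Full forward pass on one molecule; sigma > 0 on every valid vertex."""
    if valid_mask is None:
        valid_mask = np.ones(L0.shape[0])
    mu, sigma, _ = _forward(
        params, config, L0[None], g_norm[None], valid_mask[None], want_cache=False
    )
    return ShiftPrediction(mu=mu[0], sigma=sigma[0], valid_mask=valid_mask)


# ----------------------------------------------------------------------
# Adam
# ----------------------------------------------------------------------

class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, clip_norm=5.0):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, grad in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grad**2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ----------------------------------------------------------------------
# Estimator
# ----------------------------------------------------------------------

class GraphConvShiftRegressor(RegressorMixin, BaseEstimator):
    """Per-atom chemical shift regressor with heteroscedastic uncertainty.

    ``X`` is a sequence of :class:`~nmrshift.graphs.MolecularGraph`; ``y`` a
    matching sequence of per-atom float arrays holding the observed shift in
    ppm and NaN at unobserved atoms.  Separate models are trained per nucleus
    (13C or 1H); the estimator itself is nucleus-agnostic — the caller masks
    ``y`` to the nuclei of interest.

    Defaults are a desk-scale profile (4 layers, width 128) that trains on a
    CPU in minutes; the published scale is ``n_layers=10, width=2048``.
    Targets are internally standardised (z-scored over observed atoms), so the
    learning rate transfers between the ~200 ppm 13C range and the ~10 ppm
    1H range; ``sigma`` is mapped back to ppm on output.

    Attributes (after :meth:`fit`)
    ------------------------------
    params_ : dict of weight arrays (best validation checkpoint).
    config_ : ModelConfig actually used.
    loss_curve_, val_loss_curve_, val_mae_curve_ : per-epoch histories.
    best_epoch_ : epoch index of the restored checkpoint.
    y_mean_, y_std_ : target standardisation constants (ppm).
    """

    def __init__(
        self,
        n_layers: int = 4,
        width: int = 128,
        head_width: int = 128,
        n_residual_blocks: int = 3,
        m_max: int = M_DEFAULT,
        epochs: int = 40,
        batch_size: int = 32,
        learning_rate: float = 3e-3,
        validation_fraction: float = 0.1,
        patience: int = 10,
        seed: int = 0,
    ):
        self.n_layers = n_layers
        self.width = width
        self.head_width = head_width
        self.n_residual_blocks = n_residual_blocks
        self.m_max = m_max
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.seed = seed

    # -- fitting -------------------------------------------------------
    def fit(self, X, y):
        X = list(X)
        y = [np.asarray(t, dtype=float) for t in y]
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        for g, t in zip(X, y):
            if len(t) != g.n_atoms:
                raise ValueError("each y entry must have one value per atom")
        if not any(np.isfinite(t).any() for t in y):
            raise ValueError("no observed shifts in y: nothing to train on")

        config = ModelConfig(
            n_layers=self.n_layers,
            width=self.width,
            head_width=self.head_width,
            m_max=self.m_max,
            n_residual_blocks=self.n_residual_blocks,
        )
        rng = np.random.default_rng(self.seed)
        feats, adj, mask, targets, obs = self._prepare(X, y)

        # standardize input feature columns over real atoms (scalar entries
        # like atomic number would otherwise dominate early activations)
        valid = mask.astype(bool)
        self.x_mean_ = feats[valid].mean(axis=0)
        self.x_std_ = feats[valid].std(axis=0)
        self.x_std_[self.x_std_ == 0] = 1.0
        feats = np.where(valid[:, :, None], (feats - self.x_mean_) / self.x_std_, 0.0)

        all_obs = targets[obs.astype(bool)]
        self.y_mean_ = float(np.mean(all_obs))
        self.y_std_ = float(np.std(all_obs)) or 1.0
        z = np.where(obs.astype(bool), (targets - self.y_mean_) / self.y_std_, np.nan)

        n = len(X)
        if self.validation_fraction > 0 and n > 2:
            n_val = max(1, int(round(self.validation_fraction * n)))
        else:
            n_val = 0
        order = rng.permutation(n)
        val_idx, tr_idx = order[:n_val], order[n_val:]
        if len(tr_idx) == 0:
            raise ValueError("not enough molecules to carve a validation set")

        params = init_params(config, rng)
        opt = _Adam(params, lr=self.learning_rate)
        self.loss_curve_, self.val_loss_curve_, self.val_mae_curve_ = [], [], []
        best = (np.inf, None, -1)
        since_best = 0

        for epoch in range(self.epochs):
            batch_losses = []
            perm = rng.permutation(tr_idx)
            for start in range(0, len(perm), self.batch_size):
                idx = perm[start : start + self.batch_size]
                mu, sigma, cache = _forward(
                    params, config, feats[idx], adj[idx], mask[idx], want_cache=True
                )
                loss, dmu, dsigma = uncertainty_loss(
                    mu, sigma, z[idx], obs[idx], return_grads=True
                )
                grads = _backward(params, config, adj[idx], cache, dmu, dsigma)
                opt.step(params, grads)
                batch_losses.append(loss)
            self.loss_curve_.append(float(np.mean(batch_losses)))

            if n_val:
                vmu, vsig, _ = _forward(params, config, feats[val_idx], adj[val_idx], mask[val_idx])
                vloss = uncertainty_loss(vmu, vsig, z[val_idx], obs[val_idx])
                vobs = obs[val_idx].astype(bool)
                vmae = (
                    float(np.mean(np.abs(z[val_idx] - vmu)[vobs])) * self.y_std_
                    if vobs.any()
                    else np.nan
                )
            else:
                vloss, vmae = self.loss_curve_[-1], np.nan
            self.val_loss_curve_.append(float(vloss))
            self.val_mae_curve_.append(vmae)

            if vloss < best[0]:
                best = (vloss, {k: v.copy() for k, v in params.items()}, epoch)
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break

        self.params_ = best[1] if best[1] is not None else params
        self.best_epoch_ = best[2]
        self.config_ = config
        self.n_features_in_ = N_FEATURES
        return self

    def _prepare(self, X, y):
        fz = MolecularGraphFeaturizer(m_max=self.m_max)
        batch: FeaturizedBatch = fz.fit(X).transform(X)
        m = self.m_max
        targets = np.full((len(X), m), np.nan)
        for i, t in enumerate(y):
            targets[i, : len(t)] = t
        obs = np.isfinite(targets).astype(float)
        return batch.features, batch.adjacency, batch.valid_mask, targets, obs

    # -- prediction ----------------------------------------------------
    def predict_dist(self, X) -> list[ShiftPrediction]:
        """Per-molecule (mu ppm, sigma ppm, mask) on the original atom count."""
        self._check_fitted()
        X = list(X)
        fz = MolecularGraphFeaturizer(m_max=self.m_max)
        batch = fz.fit(X).transform(X)
        valid = batch.valid_mask.astype(bool)
        batch.features = np.where(
            valid[:, :, None], (batch.features - self.x_mean_) / self.x_std_, 0.0
        )
        out = []
        bs = max(1, self.batch_size)
        for start in range(0, len(X), bs):
            sl = slice(start, start + bs)
            mu, sigma, _ = _forward(
                self.params_, self.config_, batch.features[sl], batch.adjacency[sl],
                batch.valid_mask[sl],
            )
            for row, graph in enumerate(X[sl]):
                n = graph.n_atoms
                out.append(
                    ShiftPrediction(
                        mu=mu[row, :n] * self.y_std_ + self.y_mean_,
                        sigma=sigma[row, :n] * self.y_std_,
                        valid_mask=np.ones(n),
                    )
                )
        return out

    def predict(self, X) -> list[np.ndarray]:
        """Per-molecule arrays of predicted shifts (ppm)."""
        return [p.mu for p in self.predict_dist(X)]

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    # -- checkpointing -------------------------------------------------
    def save(self, path):
        """Single-file checkpoint: JSON config header + array blob (.npz)."""
        self._check_fitted()
        header = {
            "config": asdict(self.config_),
            "y_mean": self.y_mean_,
            "y_std": self.y_std_,
            "x_mean": self.x_mean_.tolist(),
            "x_std": self.x_std_.tolist(),
            "estimator_params": self.get_params(),
        }
        np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
                 **self.params_)

    @classmethod
    def load(cls, path) -> "GraphConvShiftRegressor":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            params = {k: data[k] for k in data.files if k != "__header__"}
        est = cls(**header["estimator_params"])
        est.config_ = ModelConfig(**header["config"])
        est.params_ = params
        est.y_mean_ = header["y_mean"]
        est.y_std_ = header["y_std"]
        est.x_mean_ = np.asarray(header["x_mean"])
        est.x_std_ = np.asarray(header["x_std"])
        est.best_epoch_ = -1
        est.loss_curve_ = []
        est.val_loss_curve_ = []
        est.val_mae_curve_ = []
        return est
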