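"""Explainable autoencoder for mutation-count matrices.

The model is a hybrid autoencoder: a nonlinear encoder (three dense hidden
layers, each with batch normalization and softplus) maps a sample's 96
channel counts to a non-negative latent vector z of width k, and a linear
decoder reconstructs the counts as ``x_hat = z @ W.T`` with an elementwise
non-negativity constraint on the 96 x k weight matrix W.  Columns of W are
the mutational signatures; z holds the exposures.

The training objective treats counts as Poisson draws and regularizes the
decoder towards a minimum-volume solution:

    L(x, x_hat) = sum( -x * log(x_hat) + x_hat ) + beta * log det(W W^T + I)

subject to W >= 0, enforced by clipping after every optimizer step.  The
log-determinant is evaluated on the k x k Gram matrix ``W^T W + I_k``, which
equals the 96 x 96 form by Sylvester's determinant identity.

Everything here is plain numpy: dense layers, batch-norm statistics, Adam
updates and the backward pass are written out explicitly, which keeps the
model dependency-light and bit-reproducible from a seed.

Numerical note: the latent activation output is multiplied by the sample's
total mutation burden (``burden_scaled_latent``, on by default).  The
encoder then only has to express *relative* signature activities of order
1/k, while the product z W^T lands on the count scale from the first epoch;
without this, a generic weight initialization starts the Poisson means
orders of magnitude below the data and gradient descent spends most of its
budget inflating scales.  The latent z reported as exposures is the scaled,
non-negative quantity.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .catalogue import ExposureMatrix, SBSCatalogue

__all__ = [
    "XAEConfig",
    "XAETrainingError",
    "PoissonMinVolumeAutoencoder",
    "poisson_nll",
    "min_volume_penalty",
    "build_model",
    "train_model",
    "encode",
    "reconstruct",
    "reconstruction_error",
]


class XAETrainingError(RuntimeError):
    """Raised when optimization diverges (non-finite loss or weights)."""


@dataclass
class XAEConfig:
    """Hyperparameters of the autoencoder and its training loop.

    Parameters
    ----------
    latent_dim : int
        Number of signatures k (width of the latent layer).
    encoder_units : tuple of int
        Widths of the three hidden encoder layers.
    beta : float
        Strength of the minimum-volume regularizer on the decoder.
    patience : int
        Early-stopping epochs without validation improvement.
    validation_fraction : float
        Fraction of training rows held out to monitor early stopping; 0
        monitors the training loss instead.
    epsilon : float
        Clamp added inside the Poisson log to keep it finite.
    latent_activation : {"softplus", "relu"}
        Non-negative activation producing z.  Softplus (default) avoids
        the hard-rectifier dead zone; with "relu" and no latent batch
        norm the latent bias starts positive for the same reason.
    l1_weights, l1_activity : float
        L1 penalties on the final encoder layer's weights and on the latent
        output; used during signature assignment.
    freeze_decoder : bool
        Train only the encoder, leaving W exactly as initialized.
    burden_scaled_latent : bool
        Multiply the latent activation by each sample's total burden.
    """

    latent_dim: int
    encoder_units: tuple[int, int, int] = (128, 64, 32)
    beta: float = 1e-3
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 1000
    patience: int = 30
    validation_fraction: float = 0.1
    seed: int = 0
    epsilon: float = 1e-7
    latent_activation: str = "softplus"
    l1_weights: float = 0.0
    l1_activity: float = 0.0
    freeze_decoder: bool = False
    burden_scaled_latent: bool = True
    latent_batchnorm: bool = False
    decoder_warm_start: str = "random"  # or "nmf" (seeded KL-NMF profiles)
    warm_start_iters: int = 200
    decoder_freeze_epochs: int = 0  # keep W fixed while the encoder settles
    lr_schedule: str = "constant"  # or "cosine" (decay to learning_rate/20)
    bn_inference: str = "batch"  # or "running" (exponential moving averages)
    bn_momentum: float = 0.9
    bn_eps: float = 1e-5

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if len(self.encoder_units) != 3 or any(u < 1 for u in self.encoder_units):
            raise ValueError("encoder_units must be three positive widths")
        if self.max_epochs < 0 or self.patience < 0:
            raise ValueError("max_epochs and patience must be non-negative")
        if self.max_epochs > 0 and self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.latent_activation not in ("softplus", "relu"):
            raise ValueError(f"unknown latent activation {self.latent_activation!r}")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError(f"unknown lr schedule {self.lr_schedule!r}")
        if self.bn_inference not in ("batch", "running"):
            raise ValueError(f"unknown bn_inference mode {self.bn_inference!r}")
        if self.decoder_warm_start not in ("random", "nmf"):
            raise ValueError(
                f"unknown decoder warm start {self.decoder_warm_start!r}")
        if min(self.beta, self.learning_rate, self.epsilon) < 0 or (
            self.l1_weights < 0 or self.l1_activity < 0
        ):
            raise ValueError("rates and penalties must be non-negative")
        if self.latent_dim > min(self.encoder_units):
            warnings.warn(
                "latent_dim exceeds the narrowest encoder layer; the "
                "bottleneck is the encoder, not the latent layer",
                stacklevel=2,
            )


def poisson_nll(x: np.ndarray, xhat: np.ndarray, epsilon: float = 1e-7) -> float:
    """Unnormalized Poisson negative log-likelihood, summed over entries.

    ``sum(xhat - x * log(xhat + epsilon))`` — the ``log x!`` term is a
    constant in ``xhat`` and is dropped.  Minimized at ``xhat == x``.
    """
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    return float(np.sum(xhat - x * np.log(xhat + epsilon)))


def min_volume_penalty(W: np.ndarray, beta: float) -> float:
    """Minimum-volume regularizer ``beta * log det(W W^T + I)``.

    Evaluated as ``beta * log det(W^T W + I_k)`` via a Cholesky
    factorization of the k x k Gram matrix; Sylvester's determinant
    identity guarantees equality with the 96 x 96 form.
    """
    W = np.asarray(W, dtype=np.float64)
    if not np.isfinite(W).all():
        raise XAETrainingError("non-finite decoder weights in volume penalty")
    gram = W.T @ W + np.eye(W.shape[1])
    chol = np.linalg.cholesky(gram)
    value = beta * 2.0 * float(np.sum(np.log(np.diag(chol))))
    if not np.isfinite(value):
        raise XAETrainingError("non-finite minimum-volume penalty")
    return value


def _kl_nmf_profiles(V: np.ndarray, k: int, rng: np.random.Generator,
                     iters: int, max_rows: int = 2000) -> np.ndarray:
    """Profile matrix (96 x k, columns sum to 1) from a short KL-NMF run.

    Multiplicative updates for the generalized Kullback-Leibler (Poisson)
    divergence, started from the given generator, on at most ``max_rows``
    randomly chosen rows of V.  Used as a decoder warm start: it lands in a
    good basin in a fraction of the gradient steps the network would need,
    while remaining a random restart (a different seed gives a different
    trajectory).
    """
    if V.shape[0] > max_rows:
        V = V[rng.choice(V.shape[0], size=max_rows, replace=False)]
    V = np.asarray(V, dtype=np.float64)
    m, c = V.shape
    E = rng.random((m, k)) + 0.1
    S = rng.random((k, c)) + 0.1
    for _ in range(iters):
        R = V / (E @ S + 1e-9)
        E *= (R @ S.T) / (S.sum(axis=1) + 1e-9)
        R = V / (E @ S + 1e-9)
        S *= (E.T @ R) / (E.sum(axis=0)[:, None] + 1e-9)
    W = S.T
    sums = W.sum(axis=0)
    return W / np.where(sums > 0, sums, 1.0)


def _softplus_sigmoid(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Softplus and its derivative (the sigmoid) from one exp evaluation."""
    e = np.exp(-np.abs(x))
    softplus = np.maximum(x, 0.0) + np.log1p(e)
    sigmoid = np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    return softplus, sigmoid


def _softplus(x: np.ndarray) -> np.ndarray:
    return _softplus_sigmoid(x)[0]


class PoissonMinVolumeAutoencoder:
    """Numpy implementation of the Poisson minimum-volume autoencoder.

    Construct with :class:`XAEConfig` (weights are initialized from the
    config seed), call :meth:`fit` on a count matrix, then :meth:`encode` /
    :meth:`reconstruct`.
    """

    def __init__(self, config: XAEConfig,
                 decoder_init: np.ndarray | None = None) -> None:
        self.config = config
        self.history: list[dict[str, float]] = []
        self.fitted = False
        rng = np.random.default_rng(config.seed)
        units = [96, *config.encoder_units]
        p: dict[str, np.ndarray] = {}
        for i in range(3):
            fan_in, fan_out = units[i], units[i + 1]
            p[f"enc{i}_W"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)
            ).astype(np.float32)
            p[f"enc{i}_b"] = np.zeros(fan_out, dtype=np.float32)
            p[f"bn{i}_gamma"] = np.ones(fan_out, dtype=np.float32)
            p[f"bn{i}_beta"] = np.zeros(fan_out, dtype=np.float32)
        k = config.latent_dim
        p["lat_W"] = rng.normal(
            0.0, np.sqrt(2.0 / units[-1]), (units[-1], k)
        ).astype(np.float32)
        # A rectified latent starts with a positive bias so that no unit is
        # born dead (zero output and zero gradient for every sample).
        lat_b0 = 0.5 if (config.latent_activation == "relu"
                         and not config.latent_batchnorm) else 0.0
        p["lat_b"] = np.full(k, lat_b0, dtype=np.float32)
        if config.latent_batchnorm:
            p["bn3_gamma"] = np.ones(k, dtype=np.float32)
            p["bn3_beta"] = np.zeros(k, dtype=np.float32)
        if decoder_init is not None:
            dec = np.asarray(decoder_init, dtype=np.float32)
            if dec.shape != (96, k):
                raise ValueError(f"decoder_init must be 96 x {k}")
            if (dec < 0).any():
                raise ValueError("decoder_init must be non-negative")
            p["dec_W"] = dec.copy()
        else:
            # Columns initialized on the probability-profile scale (sum ~ 1).
            raw = np.abs(rng.normal(0.0, 1.0, (96, k))) + 1e-2
            p["dec_W"] = (raw / raw.sum(axis=0)).astype(np.float32)
        self.params = p
        bn_dims = {i: units[i + 1] for i in range(3)}
        if config.latent_batchnorm:
            bn_dims[3] = k
        self.running = {
            f"bn{i}_{s}": (np.zeros(d, dtype=np.float32) if s == "mean"
                           else np.ones(d, dtype=np.float32))
            for i, d in bn_dims.items() for s in ("mean", "var")
        }

    # -- forward -----------------------------------------------------------

    @property
    def W(self) -> np.ndarray:
        """Decoder weight matrix (96 x k), the unnormalized signatures."""
        return np.asarray(self.params["dec_W"], dtype=float).copy()

    def _latent_scale(self, X: np.ndarray) -> np.ndarray:
        if self.config.burden_scaled_latent:
            return np.maximum(X.sum(axis=1, keepdims=True), 1.0)
        return np.ones((X.shape[0], 1), dtype=X.dtype)

    def _forward(self, X: np.ndarray, training: bool) -> dict:
        p, cfg = self.params, self.config
        cache: dict = {"X": X, "h": [X], "ah": [], "sig": [], "inv": []}
        h = X
        use_batch_stats = training or cfg.bn_inference == "batch"
        for i in range(3):
            a = h @ p[f"enc{i}_W"] + p[f"enc{i}_b"]
            if use_batch_stats:
                mu = a.mean(axis=0)
                var = a.var(axis=0)
                if training:
                    mom = cfg.bn_momentum
                    self.running[f"bn{i}_mean"] = (
                        mom * self.running[f"bn{i}_mean"] + (1 - mom) * mu
                    ).astype(np.float32)
                    self.running[f"bn{i}_var"] = (
                        mom * self.running[f"bn{i}_var"] + (1 - mom) * var
                    ).astype(np.float32)
            else:
                mu = self.running[f"bn{i}_mean"]
                var = self.running[f"bn{i}_var"]
            inv = 1.0 / np.sqrt(var + cfg.bn_eps)
            ah = (a - mu) * inv
            o = p[f"bn{i}_gamma"] * ah + p[f"bn{i}_beta"]
            h, sig = _softplus_sigmoid(o)
            cache["ah"].append(ah)
            cache["sig"].append(sig)
            cache["inv"].append(inv)
            cache["h"].append(h)
        z_lin = h @ p["lat_W"] + p["lat_b"]
        if cfg.latent_batchnorm:
            if use_batch_stats:
                mu = z_lin.mean(axis=0)
                var = z_lin.var(axis=0)
                if training:
                    mom = cfg.bn_momentum
                    self.running["bn3_mean"] = (
                        mom * self.running["bn3_mean"] + (1 - mom) * mu
                    ).astype(np.float32)
                    self.running["bn3_var"] = (
                        mom * self.running["bn3_var"] + (1 - mom) * var
                    ).astype(np.float32)
            else:
                mu = self.running["bn3_mean"]
                var = self.running["bn3_var"]
            z_inv = 1.0 / np.sqrt(var + cfg.bn_eps)
            z_ah = (z_lin - mu) * z_inv
            z_pre = p["bn3_gamma"] * z_ah + p["bn3_beta"]
            cache["z_ah"] = z_ah
            cache["z_inv"] = z_inv
        else:
            z_pre = z_lin
        if cfg.latent_activation == "softplus":
            z0, z_sig = _softplus_sigmoid(z_pre)
        else:
            z0 = np.maximum(z_pre, 0.0)
            z_sig = (z_pre > 0).astype(z_pre.dtype)
        cache["z_sig"] = z_sig
        scale = self._latent_scale(X)
        z = z0 * scale
        xhat = z @ p["dec_W"].T
        cache.update(z_pre=z_pre, z0=z0, z=z, scale=scale, xhat=xhat)
        return cache

    # -- loss and gradients ------------------------------------------------

    def _loss_terms(self, X: np.ndarray, cache: dict) -> tuple[float, float]:
        """(per-sample mean Poisson NLL, penalty terms)."""
        cfg = self.config
        nll = poisson_nll(X, cache["xhat"], cfg.epsilon) / X.shape[0]
        pen = 0.0
        if not cfg.freeze_decoder and cfg.beta > 0:
            pen += min_volume_penalty(self.params["dec_W"], cfg.beta)
        if cfg.l1_weights > 0:
            pen += cfg.l1_weights * float(np.abs(self.params["lat_W"]).sum())
        if cfg.l1_activity > 0:
            pen += cfg.l1_activity * float(cache["z"].sum()) / X.shape[0]
        return nll, pen

    def _backward(self, X: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        p, cfg = self.params, self.config
        B = X.shape[0]
        grads: dict[str, np.ndarray] = {}
        dxhat = (1.0 - X / (cache["xhat"] + cfg.epsilon)) / B
        z = cache["z"]
        if not cfg.freeze_decoder:
            gW = dxhat.T @ z
            if cfg.beta > 0:
                Wd = p["dec_W"].astype(np.float64)
                gram = Wd.T @ Wd + np.eye(Wd.shape[1])
                gW = gW + (2.0 * cfg.beta) * np.linalg.solve(gram, Wd.T).T
            grads["dec_W"] = gW.astype(np.float32)
        dz = dxhat @ p["dec_W"]
        if cfg.l1_activity > 0:
            dz = dz + cfg.l1_activity / B  # z >= 0, so d|z|/dz = 1 where active
        dz0 = dz * cache["scale"]
        dz_pre = dz0 * cache["z_sig"]
        if cfg.latent_batchnorm:
            z_ah = cache["z_ah"]
            grads["bn3_gamma"] = (dz_pre * z_ah).sum(axis=0).astype(np.float32)
            grads["bn3_beta"] = dz_pre.sum(axis=0).astype(np.float32)
            dah = dz_pre * p["bn3_gamma"]
            dz_lin = (cache["z_inv"] / B) * (
                B * dah - dah.sum(axis=0) - z_ah * (dah * z_ah).sum(axis=0)
            )
        else:
            dz_lin = dz_pre
        h_last = cache["h"][3]
        gl = h_last.T @ dz_lin
        if cfg.l1_weights > 0:
            gl = gl + cfg.l1_weights * np.sign(p["lat_W"])
        grads["lat_W"] = gl.astype(np.float32)
        grads["lat_b"] = dz_lin.sum(axis=0).astype(np.float32)
        dh = dz_lin @ p["lat_W"].T
        for i in reversed(range(3)):
            do = dh * cache["sig"][i]
            grads[f"bn{i}_gamma"] = (do * cache["ah"][i]).sum(axis=0).astype(np.float32)
            grads[f"bn{i}_beta"] = do.sum(axis=0).astype(np.float32)
            dah = do * p[f"bn{i}_gamma"]
            ah = cache["ah"][i]
            da = (cache["inv"][i] / B) * (
                B * dah - dah.sum(axis=0) - ah * (dah * ah).sum(axis=0)
            )
            grads[f"enc{i}_W"] = (cache["h"][i].T @ da).astype(np.float32)
            grads[f"enc{i}_b"] = da.sum(axis=0).astype(np.float32)
            dh = da @ p[f"enc{i}_W"].T
        return grads

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray | SBSCatalogue) -> "PoissonMinVolumeAutoencoder":
        """Train by minibatch Adam with early stopping; returns self.

        A ``validation_fraction`` split of rows monitors the loss; the
        parameters from the best validation epoch are restored.  The
        non-negativity of the decoder is re-imposed by clipping after every
        update, so ``W >= 0`` holds at all times.
        """
        cfg = self.config
        if isinstance(X, SBSCatalogue):
            X = X.counts
        X = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
        if X.ndim != 2 or X.shape[1] != 96 or X.shape[0] == 0:
            raise ValueError(f"training matrix must be non-empty m x 96, got {X.shape}")
        if cfg.max_epochs == 0:
            self.fitted = True
            return self
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5F17]))
        n = X.shape[0]
        n_val = int(round(cfg.validation_fraction * n))
        n_val = min(n_val, n - 1)
        order = rng.permutation(n)
        X_val, X_train = X[order[:n_val]], X[order[n_val:]]
        if (cfg.decoder_warm_start == "nmf" and not cfg.freeze_decoder
                and not self.fitted):
            self.params["dec_W"][...] = _kl_nmf_profiles(
                X_train, cfg.latent_dim, rng, cfg.warm_start_iters
            ).astype(np.float32)

        # Flatten all trainable parameters into one contiguous buffer so the
        # Adam update is a handful of vectorized ops instead of per-array
        # Python loops; self.params entries become views into the buffer.
        keys = list(self.params)
        sizes = {k: self.params[k].size for k in keys}
        flat = np.concatenate([self.params[k].ravel() for k in keys])
        views: dict[str, np.ndarray] = {}
        offset = 0
        for k in keys:
            views[k] = flat[offset:offset + sizes[k]].reshape(self.params[k].shape)
            offset += sizes[k]
        self.params = views
        g_flat = np.zeros_like(flat)
        g_views = {k: g_flat[sum(sizes[q] for q in keys[:j]):
                             sum(sizes[q] for q in keys[:j]) + sizes[k]
                             ].reshape(views[k].shape)
                   for j, k in enumerate(keys)}
        m_flat = np.zeros_like(flat)
        v_flat = np.zeros_like(flat)
        step = 0
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr0 = cfg.learning_rate
        best = np.inf
        best_state: tuple | None = None
        stale = 0
        batch = max(1, min(cfg.batch_size, X_train.shape[0]))
        for epoch in range(cfg.max_epochs):
            if cfg.lr_schedule == "cosine":
                floor = lr0 / 20.0
                lr = floor + 0.5 * (lr0 - floor) * (
                    1.0 + np.cos(np.pi * epoch / cfg.max_epochs))
            else:
                lr = lr0
            perm = rng.permutation(X_train.shape[0])
            epoch_nll = 0.0
            for start in range(0, X_train.shape[0], batch):
                xb = X_train[perm[start:start + batch]]
                cache = self._forward(xb, training=True)
                g_flat[:] = 0.0
                grads = self._backward(xb, cache)
                dec_frozen = cfg.freeze_decoder or epoch < cfg.decoder_freeze_epochs
                for key, g in grads.items():
                    if dec_frozen and key == "dec_W":
                        continue
                    g_views[key][...] = g
                step += 1
                corr = np.sqrt(1 - b2 ** step) / (1 - b1 ** step)
                m_flat *= b1
                m_flat += (1 - b1) * g_flat
                v_flat *= b2
                v_flat += (1 - b2) * g_flat * g_flat
                flat -= (lr * corr) * m_flat / (np.sqrt(v_flat) + eps)
                if not cfg.freeze_decoder:
                    np.maximum(views["dec_W"], 0.0, out=views["dec_W"])
                epoch_nll += poisson_nll(xb, cache["xhat"], cfg.epsilon)
            train_nll = epoch_nll / X_train.shape[0]
            monitor_X = X_val if n_val > 0 else X_train
            cache_m = self._forward(monitor_X, training=False)
            nll_m, pen_m = self._loss_terms(monitor_X, cache_m)
            monitored = nll_m + pen_m
            if not np.isfinite(monitored) or not np.isfinite(train_nll):
                raise XAETrainingError(
                    f"non-finite loss at epoch {epoch} "
                    f"(train {train_nll}, monitored {monitored}); "
                    "reduce the learning rate or check the input counts"
                )
            self.history.append({
                "epoch": float(epoch), "train_nll": train_nll,
                "monitored_loss": monitored,
            })
            if monitored < best - 1e-9:
                best = monitored
                best_state = (copy.deepcopy(self.params),
                              copy.deepcopy(self.running))
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        if best_state is not None:
            self.params, self.running = best_state
        self.fitted = True
        return self

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint to ``<path>.npz``-style archive: config JSON + arrays."""
        import json as _json

        from dataclasses import asdict as _asdict

        arrays = {f"param__{k}": v for k, v in self.params.items()}
        arrays.update({f"running__{k}": v for k, v in self.running.items()})
        cfg = _asdict(self.config)
        cfg["encoder_units"] = list(cfg["encoder_units"])
        np.savez(path, __config__=np.frombuffer(
            _json.dumps(cfg).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "PoissonMinVolumeAutoencoder":
        import json as _json

        with np.load(path) as archive:
            cfg = _json.loads(archive["__config__"].tobytes().decode())
            cfg["encoder_units"] = tuple(cfg["encoder_units"])
            model = cls(XAEConfig(**cfg))
            for key in archive.files:
                if key.startswith("param__"):
                    model.params[key[len("param__"):]] = archive[key]
                elif key.startswith("running__"):
                    model.running[key[len("running__"):]] = archive[key]
        model.fitted = True
        return model

    def history_frame(self):
        """Training history as a DataFrame (write with ``.to_csv``)."""
        import pandas as pd

        return pd.DataFrame(self.history)

    # -- inference ---------------------------------------------------------

    def _as_matrix(self, C: np.ndarray | SBSCatalogue) -> np.ndarray:
        X = C.counts if isinstance(C, SBSCatalogue) else np.asarray(C)
        if X.ndim != 2 or X.shape[1] != 96:
            raise ValueError(f"expected an m x 96 matrix, got shape {X.shape}")
        return np.ascontiguousarray(X.astype(np.float32))

    def transform(self, C: np.ndarray | SBSCatalogue) -> np.ndarray:
        """Latent exposures z (m x k), inference-mode batch statistics."""
        return self._forward(self._as_matrix(C), training=False)["z"].astype(float)

    def predict(self, C: np.ndarray | SBSCatalogue) -> np.ndarray:
        """Reconstructed Poisson means ``x_hat = z W^T`` (m x 96)."""
        return self._forward(self._as_matrix(C), training=False)["xhat"].astype(float)


# ---------------------------------------------------------------------------
# Functional surface


def build_model(config: XAEConfig,
                decoder_init: np.ndarray | None = None
                ) -> PoissonMinVolumeAutoencoder:
    """Construct an untrained autoencoder from ``config`` (seeded init)."""
    return PoissonMinVolumeAutoencoder(config, decoder_init=decoder_init)


def train_model(model: PoissonMinVolumeAutoencoder,
                C_train: SBSCatalogue | np.ndarray,
                config: XAEConfig | None = None) -> PoissonMinVolumeAutoencoder:
    """Train ``model`` on ``C_train``; ``config`` overrides the model's."""
    if config is not None:
        model.config = config
    return model.fit(C_train)


def encode(model: PoissonMinVolumeAutoencoder, C: SBSCatalogue) -> ExposureMatrix:
    """Exposures of ``C`` under the trained model, as an ExposureMatrix."""
    z = model.transform(C)
    ids = [f"XAE{i + 1}" for i in range(model.config.latent_dim)]
    return ExposureMatrix(np.maximum(z, 0.0), list(C.sample_ids), ids)


def reconstruct(model: PoissonMinVolumeAutoencoder, C: SBSCatalogue) -> np.ndarray:
    return model.predict(C)


def reconstruction_error(model: PoissonMinVolumeAutoencoder,
                         C: SBSCatalogue | np.ndarray) -> float:
    """Frobenius norm ``||C - C_pred||_F`` on the given catalogue."""
    X = C.counts if isinstance(C, SBSCatalogue) else np.asarray(C, dtype=float)
    return float(np.linalg.norm(X - model.predict(X), ord="fro"))
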