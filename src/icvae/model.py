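"""Interpretable conditional VAE over one-hot SMILES matrices.

The network is a convolutional encoder (three 1-D convolutions with 16, 32
and 64 filters, window 11, stride 2, acting along the string axis with the
vocabulary rows as channels), a dense bottleneck of width 292 producing the
K-dimensional posterior mean and log-scale, and a symmetric decoder (two
dense layers followed by three transposed 1-D convolutions ending in a
per-position softmax over the vocabulary).

Conditioning: the scaled property labels (condition units, range [0, 500])
are tiled along the string axis as extra input channels to the encoder
convolutions, appended to the encoder's dense bottleneck input, and
appended to the latent vector at the decoder input.

The training objective is the negative evidence lower bound with a
*shifted-mean* Gaussian prior: instead of regularizing the posterior
q(z|x,c) = N(mu, diag sigma^2) toward N(0, I), the prior for the first P
latent coordinates is centred at the scaled condition label tau*c (one
property per coordinate), N(tau*c_embed, I) overall:

    loss = E_q[-log p(x|z,c)] + beta * KL[N(mu, diag sigma^2) || N(m, I)],
    m = (tau*c_1, ..., tau*c_P, 0, ..., 0).

Equivalently the shifted variable z - tau*c is pulled toward a standard
normal, which makes latent coordinate i a linear readout of property i.
With all labels zero the objective reduces exactly to the ordinary
conditional-VAE loss.

Everything (forward, analytic gradients, Adam) is implemented on NumPy
arrays; gradients are verified against finite differences in the test
suite.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .codec import TokenVocabulary
from .properties import PropertySpec

LOG_SIGMA_MIN = np.log(1e-3)
LOG_SIGMA_MAX = np.log(1e3)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    vocab_size: int
    P: int
    K: int = 128
    hidden_dim: int = 292
    conv_filters: tuple[int, int, int] = (16, 32, 64)
    kernel: int = 11
    stride: int = 2
    max_len: int = 120
    beta: float = 1.0

    def __post_init__(self):
        if self.P > self.K:
            raise ValueError("number of conditioned properties P must be <= K")
        if min(self.vocab_size, self.K, self.hidden_dim, self.max_len) <= 0:
            raise ValueError("all dimensions must be positive")
        for L in self.conv_lengths[1:]:
            if L <= 0:
                raise ValueError(
                    f"max_len {self.max_len} too short for kernel "
                    f"{self.kernel} / stride {self.stride} stack"
                )

    @property
    def conv_lengths(self) -> tuple[int, int, int, int]:
        """Sequence lengths (input, after conv1, conv2, conv3)."""
        Ls = [self.max_len]
        for _ in range(3):
            Ls.append((Ls[-1] - self.kernel) // self.stride + 1)
        return tuple(Ls)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_filters"] = list(self.conv_filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["conv_filters"] = tuple(d["conv_filters"])
        return cls(**d)


@dataclass(frozen=True)
class LatentState:
    mu: np.ndarray
    sigma: np.ndarray
    z: np.ndarray


@dataclass(frozen=True)
class LossBreakdown:
    recon: float
    kl: float
    beta: float

    @property
    def total(self) -> float:
        return self.recon + self.beta * self.kl


# --------------------------------------------------------------------------
# closed-form shifted KL
# --------------------------------------------------------------------------

def kl_shifted(
    mu: np.ndarray, sigma: np.ndarray, prior_mean: np.ndarray
) -> float | np.ndarray:
    """KL[N(mu, diag sigma^2) || N(prior_mean, I)] in nats.

    Closed form per coordinate: -log sigma + (sigma^2 + (mu - m)^2 - 1)/2.
    For 1-D inputs returns a scalar; for (B, K) inputs a length-B vector.
    """
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    prior_mean = np.asarray(prior_mean, dtype=np.float64)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    per_coord = -np.log(sigma) + 0.5 * (sigma**2 + (mu - prior_mean) ** 2 - 1.0)
    total = per_coord.sum(axis=-1)
    return float(total) if np.ndim(total) == 0 else total


def reparameterize(
    mu: np.ndarray, sigma: np.ndarray, eps: np.ndarray | int | None = None
) -> np.ndarray:
    """z = mu + sigma (.) eps; eps may be an array, a seed, or None (seed 0)."""
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    if eps is None or isinstance(eps, (int, np.integer)):
        rng = np.random.default_rng(0 if eps is None else int(eps))
        eps = rng.standard_normal(mu.shape)
    return mu + sigma * np.asarray(eps, dtype=np.float64)


# --------------------------------------------------------------------------
# layers (forward caches what backward needs; backward accumulates grads)
# --------------------------------------------------------------------------

class _Dense:
    def __init__(self, rng, d_in, d_out, zero_cols: Sequence[int] = ()):
        scale = 1.0 / np.sqrt(d_in)
        self.W = rng.uniform(-scale, scale, size=(d_in, d_out))
        # condition-facing inputs carry values up to 500; start their weights
        # at zero so initialization is scale-free and the path is learned
        for c in zero_cols:
            self.W[c, :] = 0.0
        self.b = np.zeros(d_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.gW += self._x.T @ g
        self.gb += g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    def params(self):
        return []


class _Conv1d:
    """Valid 1-D convolution along the last axis, stride s; x: (B, C, L)."""

    def __init__(self, rng, c_in, c_out, kernel, stride, zero_channels=()):
        scale = 1.0 / np.sqrt(c_in * kernel)
        self.W = rng.uniform(-scale, scale, size=(c_out, c_in, kernel))
        for c in zero_channels:
            self.W[:, c, :] = 0.0
        self.b = np.zeros(c_out)
        self.stride = stride
        self.kernel = kernel
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x):
        k, s = self.kernel, self.stride
        cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)[:, :, ::s, :]
        self._cols = cols
        self._in_shape = x.shape
        out = np.einsum("ock,bctk->bot", self.W, cols, optimize=True)
        return out + self.b[None, :, None]

    def backward(self, g):
        k, s = self.kernel, self.stride
        self.gW += np.einsum("bot,bctk->ock", g, self._cols, optimize=True)
        self.gb += g.sum(axis=(0, 2))
        dx = np.zeros(self._in_shape)
        # dx[b, c, t*s + j] += sum_o g[b, o, t] * W[o, c, j]
        contrib = np.einsum("bot,ocj->bcjt", g, self.W, optimize=True)
        T_out = g.shape[2]
        for j in range(k):
            dx[:, :, j : j + (T_out - 1) * s + 1 : s] += contrib[:, :, j, :]
        return dx

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class _ConvT1d:
    """Transposed 1-D convolution, stride s, to an explicit target length."""

    def __init__(self, rng, c_in, c_out, kernel, stride, target_len):
        scale = 1.0 / np.sqrt(c_in * kernel)
        self.W = rng.uniform(-scale, scale, size=(c_in, c_out, kernel))
        self.b = np.zeros(c_out)
        self.stride = stride
        self.kernel = kernel
        self.target_len = target_len
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x):
        k, s = self.kernel, self.stride
        B, _, T = x.shape
        covered = (T - 1) * s + k
        if covered > self.target_len:
            raise ValueError("transposed conv overshoots target length")
        self._x = x
        out = np.zeros((B, self.W.shape[1], self.target_len))
        contrib = np.einsum("cok,bct->bokt", self.W, x, optimize=True)
        for j in range(k):
            out[:, :, j : j + (T - 1) * s + 1 : s] += contrib[:, :, j, :]
        return out + self.b[None, :, None]

    def backward(self, g):
        k, s = self.kernel, self.stride
        T = self._x.shape[2]
        dcontrib = np.stack(
            [g[:, :, j : j + (T - 1) * s + 1 : s] for j in range(k)], axis=2
        )  # (B, c_out, k, T)
        self.gW += np.einsum("bokt,bct->cok", dcontrib, self._x, optimize=True)
        self.gb += g.sum(axis=(0, 2))
        return np.einsum("cok,bokt->bct", self.W, dcontrib, optimize=True)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------

class ICVAE:
    """Encoder + shifted-prior latent + decoder, trained by Adam on NumPy."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        V, P, K, H = config.vocab_size, config.P, config.K, config.hidden_dim
        f1, f2, f3 = config.conv_filters
        k, s = config.kernel, config.stride
        L0, L1, L2, L3 = config.conv_lengths

        cond_channels = range(V, V + P)
        self.enc_conv1 = _Conv1d(rng, V + P, f1, k, s, zero_channels=cond_channels)
        self.enc_conv2 = _Conv1d(rng, f1, f2, k, s)
        self.enc_conv3 = _Conv1d(rng, f2, f3, k, s)
        flat = f3 * L3
        self.enc_dense = _Dense(rng, flat + P, H, zero_cols=range(flat, flat + P))
        self.enc_mu = _Dense(rng, H, K)
        self.enc_logsig = _Dense(rng, H, K)

        dec_in = K + P
        zero_dec = list(range(P)) + list(range(K, K + P))
        self.dec_dense1 = _Dense(rng, dec_in, H, zero_cols=zero_dec)
        self.dec_dense2 = _Dense(rng, H, flat)
        self.dec_convt3 = _ConvT1d(rng, f3, f2, k, s, target_len=L2)
        self.dec_convt2 = _ConvT1d(rng, f2, f1, k, s, target_len=L1)
        self.dec_convt1 = _ConvT1d(rng, f1, V, k, s, target_len=L0)
        self.enc_relu = [_ReLU() for _ in range(4)]
        self.dec_relu = [_ReLU() for _ in range(4)]

    # -- parameter plumbing -------------------------------------------------

    def _layers(self):
        return [
            self.enc_conv1, self.enc_conv2, self.enc_conv3,
            self.enc_dense, self.enc_mu, self.enc_logsig,
            self.dec_dense1, self.dec_dense2,
            self.dec_convt3, self.dec_convt2, self.dec_convt1,
        ]

    def parameters(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for _, g in self.parameters():
            g[...] = 0.0

    # -- forward pieces -----------------------------------------------------

    @staticmethod
    def _as_batch(a, ndim):
        a = np.asarray(a, dtype=np.float64)
        if a.ndim == ndim - 1:
            return a[None], True
        return a, False

    def _check_shapes(self, x, c):
        cfg = self.config
        if x.shape[1:] != (cfg.vocab_size, cfg.max_len):
            raise ValueError(
                f"input matrix shape {x.shape[1:]} != "
                f"({cfg.vocab_size}, {cfg.max_len})"
            )
        if c.shape[1:] != (cfg.P,):
            raise ValueError(f"condition vector length {c.shape[1:]} != ({cfg.P},)")

    def _encode_forward(self, x, c):
        cfg = self.config
        tiles = np.repeat(c[:, :, None], cfg.max_len, axis=2)
        h = np.concatenate([x, tiles], axis=1)
        h = self.enc_relu[0].forward(self.enc_conv1.forward(h))
        h = self.enc_relu[1].forward(self.enc_conv2.forward(h))
        h = self.enc_relu[2].forward(self.enc_conv3.forward(h))
        self._conv_out_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = np.concatenate([h, c], axis=1)
        h = self.enc_relu[3].forward(self.enc_dense.forward(h))
        mu = self.enc_mu.forward(h)
        logsig_raw = self.enc_logsig.forward(h)
        logsig = np.clip(logsig_raw, LOG_SIGMA_MIN, LOG_SIGMA_MAX)
        self._logsig_clip_mask = (logsig_raw > LOG_SIGMA_MIN) & (
            logsig_raw < LOG_SIGMA_MAX
        )
        return mu, logsig

    def _encode_backward(self, dmu, dlogsig):
        cfg = self.config
        dlogsig = dlogsig * self._logsig_clip_mask
        dh = self.enc_mu.backward(dmu) + self.enc_logsig.backward(dlogsig)
        dh = self.enc_dense.backward(self.enc_relu[3].backward(dh))
        dh = dh[:, : -cfg.P] if cfg.P else dh
        dh = dh.reshape(self._conv_out_shape)
        dh = self.enc_conv3.backward(self.enc_relu[2].backward(dh))
        dh = self.enc_conv2.backward(self.enc_relu[1].backward(dh))
        self.enc_conv1.backward(self.enc_relu[0].backward(dh))

    def _decode_forward(self, z, c):
        cfg = self.config
        f3 = cfg.conv_filters[2]
        L3 = cfg.conv_lengths[3]
        h = np.concatenate([z, c], axis=1)
        h = self.dec_relu[0].forward(self.dec_dense1.forward(h))
        h = self.dec_relu[1].forward(self.dec_dense2.forward(h))
        h = h.reshape(h.shape[0], f3, L3)
        h = self.dec_relu[2].forward(self.dec_convt3.forward(h))
        h = self.dec_relu[3].forward(self.dec_convt2.forward(h))
        logits = self.dec_convt1.forward(h)
        return logits

    def _decode_backward(self, dlogits):
        cfg = self.config
        dh = self.dec_convt1.backward(dlogits)
        dh = self.dec_convt2.backward(self.dec_relu[3].backward(dh))
        dh = self.dec_convt3.backward(self.dec_relu[2].backward(dh))
        dh = dh.reshape(dh.shape[0], -1)
        dh = self.dec_dense2.backward(self.dec_relu[1].backward(dh))
        dh = self.dec_dense1.backward(self.dec_relu[0].backward(dh))
        dz = dh[:, : cfg.K]
        return dz

    # -- public API ---------------------------------------------------------

    def encode(self, x, c):
        """Posterior (mu, sigma) for one-hot input x and scaled labels c."""
        x, single = self._as_batch(x, 3)
        c, _ = self._as_batch(c, 2)
        self._check_shapes(x, c)
        mu, logsig = self._encode_forward(x, c)
        sigma = np.exp(logsig)
        return (mu[0], sigma[0]) if single else (mu, sigma)

    def decode(self, z, c):
        """Per-position probabilities over the vocabulary, columns sum to 1."""
        z, single = self._as_batch(z, 2)
        c, _ = self._as_batch(c, 2)
        if z.shape[1] != self.config.K:
            raise ValueError(f"latent dim {z.shape[1]} != K={self.config.K}")
        if c.shape[1] != self.config.P:
            raise ValueError(f"condition length {c.shape[1]} != P={self.config.P}")
        logits = self._decode_forward(z, c)
        probs = _softmax_columns(logits)
        return probs[0] if single else probs

    def prior_mean(self, c):
        """Embed scaled labels into latent space: coordinate i <- label i."""
        c, single = self._as_batch(c, 2)
        m = np.zeros((c.shape[0], self.config.K))
        m[:, : self.config.P] = c
        return m[0] if single else m

    def loss(
        self,
        x,
        c,
        eps: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
        backward: bool = False,
        shift_prior: bool = True,
    ) -> LossBreakdown:
        """Mean negative ELBO over the batch (recon + beta * shifted KL).

        recon: per-position categorical cross-entropy summed over all
        max_len positions, averaged over the batch. kl: shifted-mean KL
        averaged over the batch. With shift_prior=False the prior mean is
        held at zero — the ordinary conditional-VAE objective on the same
        weights (conditions still feed the encoder and decoder). With
        backward=True, gradients accumulate into the layer .gW/.gb buffers.
        """
        x, _ = self._as_batch(x, 3)
        c, _ = self._as_batch(c, 2)
        if x.shape[0] == 0:
            raise ValueError("empty batch")
        self._check_shapes(x, c)
        B = x.shape[0]
        beta = self.config.beta

        mu, logsig = self._encode_forward(x, c)
        sigma = np.exp(logsig)
        if eps is None:
            rng = rng or np.random.default_rng(0)
            eps = rng.standard_normal(mu.shape)
        z = mu + sigma * eps

        logits = self._decode_forward(z, c)
        probs = _softmax_columns(logits)
        recon = -np.sum(x * np.log(np.clip(probs, 1e-300, None))) / B

        m = np.zeros_like(mu)
        if shift_prior:
            m[:, : self.config.P] = c
        kl_per = kl_shifted(mu, sigma, m)
        kl = float(np.mean(kl_per))

        if backward:
            dlogits = (probs - x) / B
            dz = self._decode_backward(dlogits)
            dmu = dz + beta * (mu - m) / B
            dlogsig = dz * sigma * eps + beta * (sigma**2 - 1.0) / B
            self._encode_backward(dmu, dlogsig)

        self._last_latent = LatentState(mu=mu, sigma=sigma, z=z)
        return LossBreakdown(recon=float(recon), kl=kl, beta=beta)

    # -- persistence ---------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p for i, (p, _) in enumerate(self.parameters())}

    def load_state_arrays(self, arrays) -> None:
        for i, (p, _) in enumerate(self.parameters()):
            p[...] = arrays[f"p{i}"]


def _softmax_columns(logits):
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam with global-norm gradient clipping."""

    def __init__(self, model: ICVAE, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8, clip_norm=5.0):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in model.parameters()]
        self.v = [np.zeros_like(p) for p, _ in model.parameters()]

    def step(self):
        params = self.model.parameters()
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g**2)) for _, g in params))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                for _, g in params:
                    g *= scale
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for (p, g), m, v in zip(params, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# --------------------------------------------------------------------------
# checkpointing: a zip holding the weight arrays plus JSON metadata
# --------------------------------------------------------------------------

def save_checkpoint(
    path,
    model: ICVAE,
    vocab: TokenVocabulary,
    specs: Sequence[PropertySpec],
    extra: dict | None = None,
) -> None:
    buf = io.BytesIO()
    np.savez(buf, **model.state_arrays())
    meta = {
        "config": model.config.to_dict(),
        "vocab": json.loads(vocab.to_json()),
        "specs": [sp.to_dict() for sp in specs],
        "extra": extra or {},
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("weights.npz", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta))


def load_checkpoint(path) -> tuple[ICVAE, TokenVocabulary, list[PropertySpec], dict]:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        arrays = np.load(io.BytesIO(zf.read("weights.npz")))
        config = ModelConfig.from_dict(meta["config"])
        model = ICVAE(config, seed=0)
        model.load_state_arrays(arrays)
    vocab = TokenVocabulary(
        tokens=tuple(meta["vocab"]["tokens"]),
        pad_token=meta["vocab"]["pad_token"],
        terminal_token=meta["vocab"]["terminal_token"],
    )
    specs = [PropertySpec.from_dict(d) for d in meta["specs"]]
    return model, vocab, specs, meta["extra"]
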