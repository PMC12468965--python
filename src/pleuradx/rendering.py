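"""Generative rendering of class-probability vectors into 2-D images.

Each sample's class-probability vector z (a point on the probability
simplex) is rendered into three small candidate images by three learned
generators:

* a Decoder-MLP (dense layers, ReLU hidden, Tanh output),
* a conditional GAN generator trained adversarially with a
  reconstruction term,
* a NeRV-style network conditioned on a positionally-encoded sample
  index t in addition to z, with pixel-shuffle upsampling.

All three are trained against a shared deterministic target encoding
T(z): a field of Gaussian "probability bumps", one anchor per class,
whose amplitudes are the class probabilities.  T(z) is a smooth,
injective map from the simplex into image space, so the rendering step
preserves class information by construction and gives every renderer a
well-defined reconstruction objective; the renderers differ only in the
mechanism that approximates it.  Rendered pixels live in [-1, 1]; the
persisted 8-bit form maps -1 -> 0 and +1 -> 255 linearly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import nnet

logger = logging.getLogger(__name__)

RENDERER_KINDS = ("decoder", "gan", "nerv")
DEFAULT_RENDER_SIZE = 32


@dataclass
class RenderedCandidateSet:
    """The three candidate images rendered for one sample."""

    sample_id: str
    label: str
    images: dict = field(default_factory=dict)  # kind -> (H, W) in [-1, 1]

    def __post_init__(self):
        unknown = set(self.images) - set(RENDERER_KINDS)
        if unknown:
            raise ValueError(f"unknown renderer kinds: {unknown}")


def _check_z(z):
    z = np.asarray(z, dtype=np.float64)
    if z.ndim == 1:
        z = z[None, :]
    if np.any(z < -1e-9) or np.any(z > 1 + 1e-9):
        raise ValueError("z entries must lie in [0, 1]")
    if np.any(np.abs(z.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("z rows must sum to 1")
    return z


def _anchors(k, h, w):
    """Class anchors: the two-class case uses opposite quadrant centers;
    K > 2 places anchors on a circle around the image center."""
    if k == 2:
        return np.array([[h / 4.0, w / 4.0], [3.0 * h / 4.0, 3.0 * w / 4.0]])
    ang = 2 * np.pi * np.arange(k) / k
    r = min(h, w) / 4.0
    return np.stack([h / 2.0 + r * np.sin(ang),
                     w / 2.0 + r * np.cos(ang)], axis=1)


def target_encoding(z, h=DEFAULT_RENDER_SIZE, w=DEFAULT_RENDER_SIZE):
    """Deterministic rendering target T(z).

    T(z)[r, c] = clip(2 * sum_k z_k * G_k(r, c) - 1, -1, 1) where G_k is
    an unnormalized Gaussian bump (sigma = H/6) at the class-k anchor.
    Pixel coordinates are taken at pixel centers (index + 0.5), so with
    symmetric z the field is symmetric under 180-degree rotation about
    the image center.  Accepts one z vector or a batch of rows.
    """
    single = np.asarray(z).ndim == 1
    z = _check_z(z)
    k = z.shape[1]
    anchors = _anchors(k, h, w)
    sigma = h / 6.0
    rr, cc = np.meshgrid(np.arange(h) + 0.5, np.arange(w) + 0.5,
                         indexing="ij")
    bumps = np.stack([
        np.exp(-(((rr - ar) ** 2 + (cc - ac) ** 2) / (2.0 * sigma ** 2)))
        for ar, ac in anchors])  # (K, H, W)
    out = np.clip(2.0 * np.tensordot(z, bumps, axes=(1, 0)) - 1.0,
                  -1.0, 1.0)
    return out[0] if single else out


def decoder_layer(h_prev, w, b, activation="relu"):
    """One dense decoder layer: sigma(W h + b).

    ``h_prev`` may be a vector or a batch of row vectors; ``w`` has shape
    (d_out, d_in) in the conventional column-acting orientation.
    """
    h_prev = np.asarray(h_prev, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    pre = h_prev @ w.T + np.asarray(b, dtype=np.float64)
    if activation == "relu":
        return np.maximum(pre, 0.0)
    if activation == "tanh":
        return np.tanh(pre)
    if activation in (None, "identity", "linear"):
        return pre
    raise ValueError(f"unknown activation {activation!r}")


def positional_encode(t, l_bands=6):
    """Fourier features of the normalized sample index t in [0, 1]:
    [sin(2^j pi t), cos(2^j pi t)] for j = 0..L-1, concatenated."""
    t = float(t)
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    freqs = (2.0 ** np.arange(l_bands)) * np.pi * t
    return np.stack([np.sin(freqs), np.cos(freqs)], axis=1).ravel()


class RendererModel:
    """A trained renderer of one kind; deterministic at inference."""

    def __init__(self, kind, net, k, h, w, seed, noise_dim=0):
        if kind not in RENDERER_KINDS:
            raise ValueError(f"unknown renderer kind {kind!r}")
        self.kind = kind
        self.net = net
        self.k, self.h, self.w = k, h, w
        self.seed = seed
        self.noise_dim = noise_dim

    def _inputs(self, z, t, noise):
        z = _check_z(z).astype(np.float32)
        n = z.shape[0]
        if self.kind == "decoder":
            return z
        if self.kind == "gan":
            if noise is None:
                noise = np.zeros((n, self.noise_dim), dtype=np.float32)
            noise = np.asarray(noise, dtype=np.float32).reshape(
                n, self.noise_dim)
            return np.concatenate([z, noise], axis=1)
        # nerv
        t = np.broadcast_to(np.asarray(t, dtype=np.float64).ravel(), (n,))
        pe = np.stack([positional_encode(ti) for ti in t]).astype(np.float32)
        return np.concatenate([pe, z], axis=1)

    def render(self, z, t=0.0, noise=None):
        """Render one z (returns (H, W)) or a batch (returns (N, H, W))."""
        single = np.asarray(z).ndim == 1
        x = self._inputs(z, t, noise)
        out = self.net.forward(x).reshape(-1, self.h, self.w)
        out = np.asarray(out, dtype=np.float64)
        return out[0] if single else out


def _feature_matrix(feature_table):
    """Accept a FeatureTable DataFrame or a raw (N, K) array of z rows."""
    if hasattr(feature_table, "columns"):
        from .backbone import feature_columns
        cols = feature_columns(feature_table, "prob")
        return feature_table[cols].to_numpy(dtype=np.float64)
    return np.asarray(feature_table, dtype=np.float64)


def _check_train_inputs(z):
    if z.shape[0] < 10:
        raise ValueError("renderer training needs at least 10 samples")
    if np.allclose(z.std(axis=0), 0.0):
        logger.warning("degenerate (constant) feature table: renderer will "
                       "memorize a single target")


def train_decoder_renderer(feature_table, h=DEFAULT_RENDER_SIZE,
                           w=DEFAULT_RENDER_SIZE, seed=42, epochs=300,
                           lr=1e-3, batch_size=64) -> RendererModel:
    """Decoder-MLP (K -> 64 -> 256 -> H*W; ReLU hidden, Tanh output)
    trained to reconstruct T(z) by mean squared error."""
    z = _check_z(_feature_matrix(feature_table))
    _check_train_inputs(z)
    k = z.shape[1]
    rng = np.random.default_rng(seed)
    net = nnet.Sequential([
        nnet.Dense(k, 64, rng), nnet.ReLU(),
        nnet.Dense(64, 256, rng), nnet.ReLU(),
        nnet.Dense(256, h * w, rng, init="glorot"), nnet.Tanh(),
    ])
    _fit_mse(net, z.astype(np.float32),
             target_encoding(z, h, w).reshape(len(z), -1).astype(np.float32),
             rng, epochs, lr, batch_size, "decoder")
    return RendererModel("decoder", net, k, h, w, seed)


def train_nerv_renderer(feature_table, h=DEFAULT_RENDER_SIZE,
                        w=DEFAULT_RENDER_SIZE, seed=42, epochs=300,
                        lr=1e-3, batch_size=64) -> RendererModel:
    """NeRV-style renderer: concat(positional_encode(t, 6), z) -> MLP ->
    (H/4, W/4) feature stack -> two x2 pixel-shuffle upsamplings -> Tanh.

    The reconstruction target T(z) is t-free; t gives each sample's
    rendering an index-conditioned pathway, as in neural video
    representations.
    """
    z = _check_z(_feature_matrix(feature_table))
    _check_train_inputs(z)
    k = z.shape[1]
    if h % 4 or w % 4:
        raise ValueError("NeRV renderer requires H and W divisible by 4")
    n = len(z)
    t = np.arange(n) / max(n - 1, 1)
    rng = np.random.default_rng(seed)
    d_in = 12 + k
    net = nnet.Sequential([
        nnet.Dense(d_in, 128, rng), nnet.ReLU(),
        nnet.Dense(128, 256, rng), nnet.ReLU(),
        nnet.Dense(256, (h // 4) * (w // 4) * 16, rng, init="glorot"),
        nnet.Reshape((16, h // 4, w // 4)),
        nnet.PixelShuffle(2), nnet.PixelShuffle(2),
        nnet.Reshape((h * w,)), nnet.Tanh(),
    ])
    model = RendererModel("nerv", net, k, h, w, seed)
    x = model._inputs(z, t, None)
    _fit_mse(net, x,
             target_encoding(z, h, w).reshape(n, -1).astype(np.float32),
             rng, epochs, lr, batch_size, "nerv")
    return model


def _fit_mse(net, x, targets, rng, epochs, lr, batch_size, tag):
    opt = nnet.Adam(net.params, net.grads, lr=lr)
    n = len(x)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            out = net.forward(x[idx])
            loss, dout = nnet.mse_loss(out, targets[idx])
            net.backward(dout.astype(np.float32))
            opt.step()
            losses.append(loss)
        if not np.isfinite(np.mean(losses)):
            raise RuntimeError(f"{tag} renderer training diverged "
                               f"(non-finite loss at epoch {epoch})")
        logger.debug("%s renderer epoch %d mse %.5f", tag, epoch,
                     float(np.mean(losses)))


def train_gan_renderer(feature_table, h=DEFAULT_RENDER_SIZE,
                       w=DEFAULT_RENDER_SIZE, seed=42, epochs=200,
                       lr=1e-3, batch_size=64, noise_dim=8,
                       recon_weight=100.0) -> RendererModel:
    """Conditional GAN renderer.

    The generator G(z, noise) is trained against a discriminator
    D(image, z) on "real" pairs (T(z), z), with generator loss
    adversarial + ``recon_weight`` * MSE-to-target.  Inference uses
    noise = 0, making rendering deterministic.
    """
    z = _check_z(_feature_matrix(feature_table))
    _check_train_inputs(z)
    k = z.shape[1]
    n = len(z)
    rng = np.random.default_rng(seed)
    gen = nnet.Sequential([
        nnet.Dense(k + noise_dim, 64, rng), nnet.ReLU(),
        nnet.Dense(64, 256, rng), nnet.ReLU(),
        nnet.Dense(256, h * w, rng, init="glorot"), nnet.Tanh(),
    ])
    disc = nnet.Sequential([
        nnet.Dense(h * w + k, 128, rng), nnet.ReLU(),
        nnet.Dense(128, 64, rng), nnet.ReLU(),
        nnet.Dense(64, 1, rng, init="glorot"),
    ])
    opt_g = nnet.Adam(gen.params, gen.grads, lr=lr)
    opt_d = nnet.Adam(disc.params, disc.grads, lr=lr)
    zf = z.astype(np.float32)
    real = target_encoding(z, h, w).reshape(n, -1).astype(np.float32)
    for epoch in range(epochs):
        order = rng.permutation(n)
        g_losses = []
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            zb, rb = zf[idx], real[idx]
            nb = rng.normal(0, 1, size=(len(idx), noise_dim)).astype(
                np.float32)
            gin = np.concatenate([zb, nb], axis=1)
            fake = gen.forward(gin)
            # --- discriminator step
            d_real = disc.forward(np.concatenate([rb, zb], axis=1))
            l_dr, d_dr = nnet.bce_with_logits(d_real, np.ones(len(idx)))
            disc.backward(d_dr.astype(np.float32))
            g_snap = [g.copy() for g in disc.grads]
            d_fake = disc.forward(np.concatenate([fake, zb], axis=1))
            l_df, d_df = nnet.bce_with_logits(d_fake, np.zeros(len(idx)))
            disc.backward(d_df.astype(np.float32))
            for g, s in zip(disc.grads, g_snap):
                g += s
            opt_d.step()
            # --- generator step: adversarial + reconstruction
            fake = gen.forward(gin)
            d_fake = disc.forward(np.concatenate([fake, zb], axis=1))
            l_adv, d_adv = nnet.bce_with_logits(d_fake, np.ones(len(idx)))
            d_in = disc.backward(d_adv.astype(np.float32))
            l_rec, d_rec = nnet.mse_loss(fake, rb)
            dfake = d_in[:, :h * w] + recon_weight * d_rec
            gen.backward(dfake.astype(np.float32))
            opt_g.step()
            g_losses.append(l_adv + recon_weight * l_rec)
        if not np.isfinite(np.mean(g_losses)):
            raise RuntimeError(f"GAN renderer training diverged at epoch "
                               f"{epoch}")
        logger.debug("gan renderer epoch %d loss %.5f", epoch,
                     float(np.mean(g_losses)))
    model = RendererModel("gan", gen, k, h, w, seed, noise_dim=noise_dim)
    model.discriminator = disc
    return model


def render_all(feature_table, renderers, h=DEFAULT_RENDER_SIZE,
               w=DEFAULT_RENDER_SIZE):
    """Render every sample with all three renderers.

    ``renderers`` maps kind -> trained RendererModel and must cover
    {decoder, gan, nerv}.  Returns one :class:`RenderedCandidateSet` per
    feature-table row, order preserved; the NeRV index t is the row's
    normalized position.
    """
    missing = set(RENDERER_KINDS) - set(renderers)
    if missing:
        raise ValueError(f"missing renderer kinds: {sorted(missing)}")
    z = _feature_matrix(feature_table)
    n = len(z)
    if n == 0:
        return []
    if hasattr(feature_table, "columns"):
        ids = list(feature_table["image_id"])
        labels = list(feature_table["label"]) \
            if "label" in feature_table.columns else [""] * n
    else:
        ids = [str(i) for i in range(n)]
        labels = [""] * n
    t = np.arange(n) / max(n - 1, 1)
    per_kind = {kind: renderers[kind].render(z, t=t)
                for kind in RENDERER_KINDS}
    return [RenderedCandidateSet(
        sample_id=ids[i], label=labels[i],
        images={kind: per_kind[kind][i] for kind in RENDERER_KINDS})
        for i in range(n)]


def to_uint8(image):
    """Map a [-1, 1] rendered image linearly to 8-bit (-1 -> 0, 1 -> 255)."""
    return np.clip(np.rint((np.asarray(image) + 1.0) * 127.5),
                   0, 255).astype(np.uint8)


def write_candidates(candidates, out_dir):
    """Persist candidates as PNG under <out>/<kind>/<label>/img_<index>.png."""
    out = Path(out_dir)
    paths = []
    for i, cand in enumerate(candidates):
        row = {}
        for kind, img in cand.images.items():
            d = out / kind / (cand.label or "unlabeled")
            d.mkdir(parents=True, exist_ok=True)
            p = d / f"img_{i}.png"
            Image.fromarray(to_uint8(img), mode="L").save(p)
            row[kind] = str(p)
        paths.append(row)
    return paths
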