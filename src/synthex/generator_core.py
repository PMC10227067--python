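"""Conditional-generator contract and a miniature trainable conditional GAN.

The contract: a generator owns one learned embedding vector per class, and
generate(seed, embeddings) consumes exactly one embedding per synthesis
layer, so class blending (interpolated embeddings) and layer blending
(different embeddings per layer) are first-class operations.

The mini cGAN is a numpy model with hand-written gradients: a 4-layer MLP
generator whose every layer receives the class embedding additively, and a
projection-style discriminator built from a frozen random-feature map with
trainable per-class linear heads. Keeping the discriminator linear in its
trainable parameters makes the R1 gradient penalty's parameter gradient
analytic (no second-order autodiff), while the generator still receives a
full adversarial input-gradient signal. Training uses the non-saturating
loss with R1 regularization (default gamma 1.6384, batch size 32).
"""

from __future__ import annotations

import json
import logging
import zipfile
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


class InterfaceError(ValueError):
    """Embedding list has the wrong length or dimension."""


class ConditioningError(ValueError):
    """Dataset cannot support class conditioning (single class)."""


class ContractError(TypeError):
    """Discriminator does not expose the gradient the penalty needs."""


@dataclass(frozen=True)
class ClassEmbedding:
    class_id: object
    vector: np.ndarray


@dataclass(frozen=True)
class GANTrainConfig:
    """Training settings for the mini cGAN."""

    r1_gamma: float = 1.6384
    batch_size: int = 32
    total_kimg: float = 10.0  # thousands of images shown
    augmentations: bool = False
    seed: int = 0
    latent_dim: int = 64
    embedding_dim: int = 32
    hidden: int = 256
    lr: float = 1e-3
    lr_disc: float = 5e-3  # linear heads tolerate a larger step
    fid_interval_kimg: float = 5.0

    def __post_init__(self):
        if self.r1_gamma < 0:
            raise ValueError("r1_gamma must be >= 0")


def seed_latent(seed: int, dim: int) -> np.ndarray:
    """Integer seed -> latent vector; part of the public contract."""
    rng = np.random.Generator(np.random.Philox([int(seed), 909]))
    return rng.standard_normal(dim)


def _lrelu(x, slope=0.2):
    return np.where(x > 0, x, slope * x)


def _lrelu_grad(x, slope=0.2):
    return np.where(x > 0, 1.0, slope)


# ---------------------------------------------------------------------------
# R1 penalty
# ---------------------------------------------------------------------------


def r1_penalty(discriminator, real_batch, gamma: float) -> float:
    """(gamma/2) * mean over the batch of ||grad_x D(x)||^2.

    The discriminator must expose grad_input(batch) -> per-sample gradients;
    anything else cannot supply the gradient and is a contract violation.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if not hasattr(discriminator, "grad_input"):
        raise ContractError(
            "discriminator must expose grad_input(batch) for the R1 penalty"
        )
    x = np.asarray(real_batch, dtype=float)
    if x.ndim == 1:
        x = x[None]
    grads = np.asarray(discriminator.grad_input(x), dtype=float)
    flat = grads.reshape(len(x), -1)
    return float(gamma / 2.0 * (flat**2).sum(axis=1).mean())


class LinearDiscriminator:
    """D(x) = <w, x> + b; analytic benchmark for the R1 penalty."""

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=float)
        self.b = float(b)

    def value(self, x):
        return np.asarray(x, dtype=float).reshape(len(x), -1) @ self.w + self.b

    def grad_input(self, x):
        return np.broadcast_to(self.w, (len(x), self.w.size)).copy()


class QuadraticDiscriminator:
    """D(x) = ||x||^2; gradient 2x."""

    def value(self, x):
        flat = np.asarray(x, dtype=float).reshape(len(x), -1)
        return (flat**2).sum(axis=1)

    def grad_input(self, x):
        return 2.0 * np.asarray(x, dtype=float).reshape(len(x), -1)


# ---------------------------------------------------------------------------
# Mini conditional GAN
# ---------------------------------------------------------------------------


class MiniCGAN:
    """4-layer conditional generator + random-feature projection discriminator.

    Generator layer l computes h_l = lrelu(W_l h_{l-1} + U_l e_l + b_l) with
    e_l the embedding handed to that layer; the output layer maps to a
    sigmoid image in [0, 1]. One learned embedding per class.
    """

    n_layers = 4

    def __init__(self, classes=("A", "B"), image_size: int = 32,
                 cfg: GANTrainConfig | None = None):
        self.cfg = cfg or GANTrainConfig()
        self.classes = tuple(classes)
        self.image_size = image_size
        self.embedding_dim = self.cfg.embedding_dim
        d_out = image_size * image_size * 3
        h = self.cfg.hidden
        zdim = self.cfg.latent_dim
        rng = np.random.Generator(np.random.Philox([self.cfg.seed, 5151]))
        self._init_rng = rng

        def winit(a, b):
            return rng.normal(0, np.sqrt(2.0 / a), (a, b))

        sizes_in = [zdim, h, h, h]
        self.W = [winit(sizes_in[l], h) for l in range(self.n_layers)]
        self.U = [winit(self.embedding_dim, h) for _ in range(self.n_layers)]
        self.b = [np.zeros(h) for _ in range(self.n_layers)]
        self.W_out = winit(h, d_out)
        self.b_out = np.zeros(d_out)
        self.embeddings = {
            c: rng.normal(0, 1.0, self.embedding_dim) for c in self.classes
        }

        # discriminator: frozen feature map + trainable per-class heads
        self._A = rng.normal(0, 1.0 / np.sqrt(d_out), (d_out, 512))
        self._a = rng.normal(0, 0.1, 512)
        self.d_heads = {c: rng.normal(0, 0.01, 512) for c in self.classes}
        self.d_bias = {c: 0.0 for c in self.classes}
        self.training_log: list[dict] = []
        # calibration metadata for the concordance pipeline
        self.tile_um = float(image_size)
        self.mpp = 1.0

    # -- contract ----------------------------------------------------------

    def embed_class(self, class_id) -> np.ndarray:
        if class_id not in self.embeddings:
            raise KeyError(f"unknown class {class_id!r}")
        return self.embeddings[class_id].copy()

    def _check_embeddings(self, embeddings):
        embs = [np.asarray(e, dtype=float) for e in embeddings]
        if len(embs) != self.n_layers:
            raise InterfaceError(
                f"expected {self.n_layers} embeddings, got {len(embs)}"
            )
        for e in embs:
            if e.shape != (self.embedding_dim,):
                raise InterfaceError(
                    f"embedding shape {e.shape} != ({self.embedding_dim},)"
                )
        return embs

    def _synthesize(self, z: np.ndarray, embs) -> tuple:
        """Forward pass; returns (image batch in [0,1], cache for backprop)."""
        pre = []
        acts = [z]
        h = z
        for l in range(self.n_layers):
            s = h @ self.W[l] + embs[l] @ self.U[l] + self.b[l]
            pre.append(s)
            h = _lrelu(s)
            acts.append(h)
        logits = h @ self.W_out + self.b_out
        img = 1.0 / (1.0 + np.exp(-logits))
        return img, (pre, acts, logits)

    def generate(self, seed: int, embeddings) -> np.ndarray:
        """Deterministic uint8 image for (weights, seed, embeddings)."""
        embs = self._check_embeddings(embeddings)
        z = seed_latent(seed, self.cfg.latent_dim)[None]
        img01, _ = self._synthesize(z, [e[None] for e in embs])
        img = img01.reshape(self.image_size, self.image_size, 3)
        return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)

    def generate_class(self, seed: int, class_id) -> np.ndarray:
        e = self.embed_class(class_id)
        return self.generate(seed, [e] * self.n_layers)

    # -- discriminator -----------------------------------------------------

    def _features(self, x_flat: np.ndarray):
        s = x_flat @ self._A + self._a
        return _lrelu(s), _lrelu_grad(s)

    def d_value(self, x_flat: np.ndarray, class_ids) -> np.ndarray:
        phi, _ = self._features(x_flat)
        w = np.stack([self.d_heads[c] for c in class_ids])
        b = np.array([self.d_bias[c] for c in class_ids])
        return (phi * w).sum(axis=1) + b

    def d_grad_input(self, x_flat: np.ndarray, class_ids) -> np.ndarray:
        """Per-sample gradient of D w.r.t. the input pixels."""
        _, sgrad = self._features(x_flat)
        w = np.stack([self.d_heads[c] for c in class_ids])
        return (sgrad * w) @ self._A.T

    class _BoundDiscriminator:
        """View of the cGAN discriminator for one class, for r1_penalty."""

        def __init__(self, parent, class_id):
            self.parent = parent
            self.class_id = class_id

        def value(self, x):
            flat = np.asarray(x, float).reshape(len(x), -1)
            return self.parent.d_value(flat, [self.class_id] * len(flat))

        def grad_input(self, x):
            flat = np.asarray(x, float).reshape(len(x), -1)
            return self.parent.d_grad_input(flat, [self.class_id] * len(flat))

    def discriminator(self, class_id):
        return self._BoundDiscriminator(self, class_id)

    # -- checkpointing -----------------------------------------------------

    def save(self, path):
        """Single-file archive: npz arrays + JSON metadata."""
        meta = {
            "classes": list(self.classes),
            "n_layers": self.n_layers,
            "embedding_dim": self.embedding_dim,
            "image_size": self.image_size,
        }
        arrays = {"W_out": self.W_out, "b_out": self.b_out, "A": self._A, "a": self._a}
        for l in range(self.n_layers):
            arrays[f"W{l}"] = self.W[l]
            arrays[f"U{l}"] = self.U[l]
            arrays[f"b{l}"] = self.b[l]
        for c in self.classes:
            arrays[f"emb_{c}"] = self.embeddings[c]
            arrays[f"dh_{c}"] = self.d_heads[c]
            arrays[f"db_{c}"] = np.array([self.d_bias[c]])
        import io as _io

        buf = _io.BytesIO()
        np.savez(buf, **arrays)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            zf.writestr("arrays.npz", buf.getvalue())

    @classmethod
    def load(cls, path, cfg: GANTrainConfig | None = None):
        import io as _io

        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            npz = np.load(_io.BytesIO(zf.read("arrays.npz")))
        model = cls(classes=tuple(meta["classes"]), image_size=meta["image_size"], cfg=cfg)
        model.W = [npz[f"W{l}"] for l in range(model.n_layers)]
        model.U = [npz[f"U{l}"] for l in range(model.n_layers)]
        model.b = [npz[f"b{l}"] for l in range(model.n_layers)]
        model.W_out, model.b_out = npz["W_out"], npz["b_out"]
        model._A, model._a = npz["A"], npz["a"]
        for c in model.classes:
            model.embeddings[c] = npz[f"emb_{c}"]
            model.d_heads[c] = npz[f"dh_{c}"]
            model.d_bias[c] = float(npz[f"db_{c}"][0])
        return model


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def train_mini_cgan(dataset, cfg: GANTrainConfig | None = None,
                    classes=None, fid_reference=None) -> MiniCGAN:
    """Train the mini cGAN with the non-saturating loss + R1 regularization.

    dataset: (images uint8 [N, s, s, 3], labels length N). The training log
    records the loss trajectory and FID checkpoints against the training set
    (or fid_reference if given).
    """
    cfg = cfg or GANTrainConfig()
    images, labels = dataset
    images = np.asarray(images)
    labels = list(labels)
    found = sorted(set(labels))
    if len(found) < 2:
        raise ConditioningError("conditioning requires at least 2 classes")
    classes = tuple(classes or found)
    size = images.shape[1]
    model = MiniCGAN(classes=classes, image_size=size, cfg=cfg)
    rng = np.random.Generator(np.random.Philox([cfg.seed, 8686]))

    x_flat = images.reshape(len(images), -1).astype(float) / 255.0
    y = np.array(labels)
    by_class = {c: np.flatnonzero(y == c) for c in classes}
    AAt = model._A.T @ model._A  # for the analytic R1 head gradient

    # start the sigmoid output at the dataset mean image, so early training
    # spends its budget on structure and class response, not global brightness
    mean_img = np.clip(x_flat.mean(axis=0), 1e-3, 1 - 1e-3)
    model.b_out = np.log(mean_img / (1.0 - mean_img))

    from synthex import fid as fid_mod

    embedder = fid_mod.default_embedder()
    ref_imgs = images if fid_reference is None else np.asarray(fid_reference)
    ref_stats = fid_mod.gaussian_stats(embedder(ref_imgs))

    def fid_now(n=256):
        seeds = rng.integers(0, 2**31 - 1, n)
        zs = np.stack([seed_latent(int(s), cfg.latent_dim) for s in seeds])
        cs = [classes[i % len(classes)] for i in range(n)]
        embs = [np.stack([model.embeddings[c] for c in cs])] * model.n_layers
        img01, _ = model._synthesize(zs, embs)
        imgs = np.clip(np.rint(img01 * 255), 0, 255).astype(np.uint8)
        imgs = imgs.reshape(n, size, size, 3)
        return fid_mod.fid(fid_mod.gaussian_stats(embedder(imgs)), ref_stats)

    model.training_log.append({"kimg": 0.0, "fid": fid_now()})

    # Adam state for generator (+ embeddings) and discriminator heads
    g_params = (
        model.W + model.U + model.b + [model.W_out, model.b_out]
    )
    adam_g = [(np.zeros_like(p), np.zeros_like(p)) for p in g_params]
    adam_e = {c: (np.zeros_like(model.embeddings[c]),
                  np.zeros_like(model.embeddings[c])) for c in classes}
    adam_d = {c: (np.zeros(512), np.zeros(512)) for c in classes}
    beta1, beta2, eps = 0.0, 0.99, 1e-8  # StyleGAN-style beta1=0

    n_steps = max(1, int(round(cfg.total_kimg * 1000 / cfg.batch_size)))
    next_fid = cfg.fid_interval_kimg
    t = 0

    def adam_step(param, grad, state, lr):
        m, v = state
        m[:] = beta1 * m + (1 - beta1) * grad
        v[:] = beta2 * v + (1 - beta2) * grad**2
        mhat = m / (1 - beta1**t)
        vhat = v / (1 - beta2**t)
        param -= lr * mhat / (np.sqrt(vhat) + eps)

    for step in range(1, n_steps + 1):
        t = step
        # -- discriminator update ------------------------------------------
        half = cfg.batch_size // 2
        cls_draw = [classes[int(i)] for i in rng.integers(0, len(classes), half)]
        real_idx = np.array([rng.choice(by_class[c]) for c in cls_draw])
        x_real = x_flat[real_idx]
        z = rng.standard_normal((half, cfg.latent_dim))
        embs = [np.stack([model.embeddings[c] for c in cls_draw])] * model.n_layers
        x_fake, _ = model._synthesize(z, embs)

        phi_r, sg_r = model._features(x_real)
        phi_f, sg_f = model._features(x_fake)
        for c in classes:
            sel = np.array([ci == c for ci in cls_draw])
            if not sel.any():
                continue
            w = model.d_heads[c]
            d_r = phi_r[sel] @ w + model.d_bias[c]
            d_f = phi_f[sel] @ w + model.d_bias[c]
            # non-saturating logistic loss
            grad_w = (
                (-_sigmoid(-d_r))[:, None] * phi_r[sel]
                + (_sigmoid(d_f))[:, None] * phi_f[sel]
            ).mean(axis=0)
            grad_b = float((-_sigmoid(-d_r) + _sigmoid(d_f)).mean())
            # analytic R1 on real samples: ||grad_x D||^2 = (s w)' A A' (s w)
            if cfg.r1_gamma > 0:
                sw = sg_r[sel] * w  # per-sample elementwise
                r1_grad = 2.0 * (sg_r[sel] * (sw @ AAt)).mean(axis=0)
                grad_w = grad_w + (cfg.r1_gamma / 2.0) * r1_grad
            adam_step(model.d_heads[c], grad_w, adam_d[c], cfg.lr_disc)
            model.d_bias[c] -= cfg.lr_disc * grad_b

        # -- generator update ----------------------------------------------
        cls_draw = [classes[int(i)] for i in rng.integers(0, len(classes), cfg.batch_size)]
        z = rng.standard_normal((cfg.batch_size, cfg.latent_dim))
        emb_mat = np.stack([model.embeddings[c] for c in cls_draw])
        embs = [emb_mat] * model.n_layers
        img, (pre, acts, logits) = model._synthesize(z, embs)
        phi, sgrad = model._features(img)
        w_mat = np.stack([model.d_heads[c] for c in cls_draw])
        b_vec = np.array([model.d_bias[c] for c in cls_draw])
        d_fake = (phi * w_mat).sum(axis=1) + b_vec
        g_loss = float(np.logaddexp(0.0, -d_fake).mean())

        # dL/d(image) then back through sigmoid output and the MLP
        dL_dD = -_sigmoid(-d_fake) / cfg.batch_size
        dL_dimg = (sgrad * w_mat) @ model._A.T * dL_dD[:, None]
        dlogits = dL_dimg * img * (1.0 - img)
        gW_out = acts[-1].T @ dlogits
        gb_out = dlogits.sum(axis=0)
        delta = dlogits @ model.W_out.T
        gW = [None] * model.n_layers
        gU = [None] * model.n_layers
        gb = [None] * model.n_layers
        g_emb = np.zeros_like(emb_mat)
        for l in reversed(range(model.n_layers)):
            delta = delta * _lrelu_grad(pre[l])
            gW[l] = acts[l].T @ delta
            gU[l] = emb_mat.T @ delta
            gb[l] = delta.sum(axis=0)
            g_emb += delta @ model.U[l].T
            if l > 0:
                delta = delta @ model.W[l].T

        for p, g, st in zip(
            model.W + model.U + model.b + [model.W_out, model.b_out],
            gW + gU + gb + [gW_out, gb_out],
            adam_g,
        ):
            adam_step(p, g, st, cfg.lr)
        for c in classes:
            sel = np.array([ci == c for ci in cls_draw])
            if sel.any():
                adam_step(model.embeddings[c], g_emb[sel].sum(axis=0), adam_e[c], cfg.lr)

        kimg = step * cfg.batch_size / 1000.0
        if kimg >= next_fid or step == n_steps:
            entry = {"kimg": kimg, "fid": fid_now(), "g_loss": g_loss}
            model.training_log.append(entry)
            log.info("cGAN %.1f kimg: FID %.2f g_loss %.3f", kimg, entry["fid"], g_loss)
            next_fid += cfg.fid_interval_kimg

    return model
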