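"""Label-conditioned GAN for dermoscopic image synthesis.

The generator maps a 256-dim standard-normal latent vector plus a lesion
class label in [0, 5] to a 128x128x3 image in [0, 1].  The latent branch is
a dense layer to 128*8*8 = 8192 units reshaped to 8x8 feature maps; the
label branch is a 64-dim embedding reshaped to one 8x8 map; their
concatenation (8x8x129) is upsampled through DCGAN-style transposed
convolutions (kernel 4, stride 2) to the output resolution, with a sigmoid
output so pixel values live on the same normalized [0, 1] scale the
post-processing threshold assumes.

The discriminator embeds the label, upscales it linearly to a full-resolution
plane concatenated with the image as a fourth channel, downsamples four
times (at the default geometry), flattens, applies 40% dropout and ends in a
single sigmoid unit.

Training alternates per epoch: the discriminator takes two separate updates
(a half batch of real images with target 1, then a half batch of generated
images with target 0), after which the generator is updated through the
combined module with the discriminator frozen and the labels reversed to 1
(the non-saturating form: the generator is rewarded when the frozen
discriminator calls its output real).

A ``scale`` below 1 shrinks spatial dimensions and filter counts
proportionally so the full loop runs on a CPU in seconds; the default
configuration reproduces the 128x128 geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam, Conv2d, ConvTranspose2d, Dense, Dropout, Embedding, Module, Tensor,
    concat,
)

__all__ = [
    "GanConfig", "Generator", "Discriminator", "GanBundle", "GanLossRecord",
    "build_generator", "build_discriminator", "discriminator_loss",
    "generator_loss", "train_epoch", "generate_batch",
    "interpolate_black_pixels", "EPS",
]

EPS = 1e-7              # probability clamp before logs
START_SIZE = 8          # spatial side of the first feature map
DCGAN_INIT_STD = 0.02   # weight init convention for both networks


@dataclass
class GanConfig:
    image_size: int = 128
    latent_dim: int = 256
    n_classes: int = 6
    base_filters: int = 128
    lr: float = 2e-4
    beta1: float = 0.5
    dropout: float = 0.40

    def __post_init__(self):
        n_up = np.log2(self.image_size / START_SIZE)
        if n_up < 1 or n_up != int(n_up):
            raise ValueError(
                f"image_size must be {START_SIZE} * 2**k with k >= 1, "
                f"got {self.image_size}")
        if self.latent_dim < 1 or self.n_classes < 2:
            raise ValueError("latent_dim >= 1 and n_classes >= 2 required")

    @property
    def n_stages(self) -> int:
        return int(np.log2(self.image_size / START_SIZE))

    @classmethod
    def desk(cls, image_size: int = 32) -> "GanConfig":
        """Proportionally scaled-down geometry for CPU runs."""
        scale = image_size / 128
        return cls(image_size=image_size,
                   latent_dim=max(int(256 * scale), 16),
                   base_filters=max(int(128 * scale), 16))


class Generator(Module):
    """Conditioned generator: (z, c) -> image in [0, 1] (NCHW internally)."""

    def __init__(self, config: GanConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        cfg = config
        self.config = cfg
        self.label_embed_dim = START_SIZE * START_SIZE  # 64 at the 8x8 start
        self.embed = Embedding(cfg.n_classes, self.label_embed_dim, rng)
        self.latent_dense = Dense(cfg.latent_dim,
                                  cfg.base_filters * START_SIZE * START_SIZE,
                                  rng, w_std=DCGAN_INIT_STD)
        # channel count entering the upsampling stack: base_filters + 1
        self.concat_channels = cfg.base_filters + 1
        filters = [max(cfg.base_filters // 2 ** ((i + 1) // 2), 8)
                   for i in range(cfg.n_stages)]
        self.upsample = []
        in_ch = self.concat_channels
        for f in filters:
            self.upsample.append(
                ConvTranspose2d(in_ch, f, 4, 2, 1, rng, w_std=DCGAN_INIT_STD))
            in_ch = f
        self.to_rgb = Conv2d(in_ch, 3, 3, 1, 1, rng, w_std=DCGAN_INIT_STD)

    def forward(self, z: Tensor | np.ndarray, labels: np.ndarray) -> Tensor:
        z = z if isinstance(z, Tensor) else Tensor(z)
        n = z.shape[0]
        h = self.latent_dense(z).leaky_relu(0.2)
        h = h.reshape(n, self.config.base_filters, START_SIZE, START_SIZE)
        lab = self.embed(labels).reshape(n, 1, START_SIZE, START_SIZE)
        x = concat([h, lab], axis=1)
        for layer in self.upsample:
            x = layer(x).leaky_relu(0.2)
        return self.to_rgb(x).sigmoid()

    def generate(self, z: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """Forward pass returning (n, H, W, 3) numpy images."""
        out = self.forward(Tensor(np.asarray(z, dtype=np.float64)), labels)
        return np.transpose(out.data, (0, 2, 3, 1))


class Discriminator(Module):
    """Conditioned discriminator: (image, c) -> probability the image is real."""

    def __init__(self, config: GanConfig, seed: int = 1):
        rng = np.random.default_rng(seed)
        cfg = config
        self.config = cfg
        self.embed = Embedding(cfg.n_classes, START_SIZE * START_SIZE, rng)
        # linear upscale of the label embedding to a full-resolution plane
        self.label_dense = Dense(START_SIZE * START_SIZE,
                                 cfg.image_size * cfg.image_size, rng,
                                 w_std=DCGAN_INIT_STD)
        # constant-width conv stack: capacity comparable to the generator's,
        # which keeps the desk-scale adversarial game near equilibrium
        filters = [cfg.base_filters] * cfg.n_stages
        self.downsample = []
        in_ch = 4  # 3 image channels + 1 label channel
        for f in filters:
            self.downsample.append(
                Conv2d(in_ch, f, 4, 2, 1, rng, w_std=DCGAN_INIT_STD))
            in_ch = f
        self.dropout = Dropout(cfg.dropout)
        self.classify = Dense(in_ch * START_SIZE * START_SIZE, 1, rng,
                              w_std=DCGAN_INIT_STD)

    def forward(self, images: Tensor | np.ndarray, labels: np.ndarray,
                rng: np.random.Generator | None = None) -> Tensor:
        """``images`` is NCHW; pass ``rng`` to enable dropout (training)."""
        x = images if isinstance(images, Tensor) else Tensor(images)
        n, _, hh, ww = x.shape
        lab = self.label_dense(self.embed(labels)).reshape(n, 1, hh, ww)
        x = concat([x, lab], axis=1)
        for layer in self.downsample:
            x = layer(x).leaky_relu(0.2)
        x = x.reshape(n, -1)
        x = self.dropout(x, rng=rng)
        return self.classify(x).sigmoid().reshape(n)


def build_generator(latent_dim: int = 256, n_classes: int = 6,
                    image_size: int = 128, base_filters: int = 128,
                    seed: int = 0) -> Generator:
    cfg = GanConfig(image_size=image_size, latent_dim=latent_dim,
                    n_classes=n_classes, base_filters=base_filters)
    return Generator(cfg, seed=seed)


def build_discriminator(n_classes: int = 6, image_size: int = 128,
                        base_filters: int = 128, seed: int = 1) -> Discriminator:
    cfg = GanConfig(image_size=image_size, n_classes=n_classes,
                    base_filters=base_filters)
    return Discriminator(cfg, seed=seed)


# -- losses -----------------------------------------------------------------

def _clamped_log(p: np.ndarray) -> np.ndarray:
    return np.log(np.clip(p, EPS, 1.0 - EPS))


def discriminator_loss(d_real, d_fake) -> tuple[float, float]:
    """Negated empirical discriminator objective, split into halves.

    Returns ``(loss_real, loss_fake)``: binary cross-entropy of the real
    probabilities against target 1 and the fake probabilities against
    target 0, each averaged over its half batch.
    """
    d_real = np.asarray(d_real, dtype=np.float64)
    d_fake = np.asarray(d_fake, dtype=np.float64)
    loss_real = float(-np.mean(_clamped_log(d_real)))
    loss_fake = float(-np.mean(_clamped_log(1.0 - d_fake)))
    return loss_real, loss_fake


def generator_loss(d_fake) -> float:
    """Non-saturating generator loss: BCE of D(G(z|c)) against target 1."""
    d_fake = np.asarray(d_fake, dtype=np.float64)
    return float(-np.mean(_clamped_log(d_fake)))


def _bce(pred: Tensor, target: float) -> Tensor:
    """Graph-building binary cross-entropy against a constant target."""
    p = pred.clip(EPS, 1.0 - EPS)
    if target == 1.0:
        return -(p.log().mean())
    if target == 0.0:
        return -((1.0 - p).log().mean())
    return -(p.log() * target + (1.0 - p).log() * (1.0 - target)).mean()


# -- bundle and training ----------------------------------------------------

@dataclass
class GanLossRecord:
    epoch: int
    g_loss: float
    d_loss_real: float
    d_loss_fake: float
    d_acc_real: float
    d_acc_fake: float

    FIELDS = ("epoch", "g_loss", "d_loss_real", "d_loss_fake",
              "d_acc_real", "d_acc_fake")


@dataclass
class GanBundle:
    """Generator + discriminator + the combined-module bookkeeping."""

    generator: Generator
    discriminator: Discriminator
    opt_g: Adam = field(init=False)
    opt_d: Adam = field(init=False)

    def __post_init__(self):
        cfg = self.generator.config
        self.opt_g = Adam(self.generator.parameters(), lr=cfg.lr,
                          beta1=cfg.beta1)
        self.opt_d = Adam(self.discriminator.parameters(), lr=cfg.lr,
                          beta1=cfg.beta1)

    @classmethod
    def build(cls, config: GanConfig | None = None, seed: int = 0) -> "GanBundle":
        cfg = config or GanConfig()
        return cls(generator=Generator(cfg, seed=seed),
                   discriminator=Discriminator(cfg, seed=seed + 1))

    def param_report(self) -> dict:
        """Trainable/non-trainable parameter bookkeeping.

        The combined module counts the generator once and the discriminator
        twice (one weight set per real/fake pass); during a generator update
        exactly one discriminator's worth of parameters is frozen.
        """
        g = self.generator.param_count()
        d = self.discriminator.param_count()
        return {
            "generator": g,
            "discriminator": d,
            "gan_total": g + 2 * d,
            "gan_trainable": g + d,
            "gan_non_trainable": d,
        }


def train_epoch(bundle: GanBundle, real_images: np.ndarray,
                real_labels: np.ndarray, epoch: int = 0, batch_size: int = 32,
                rng: np.random.Generator | int | None = None) -> GanLossRecord:
    """One alternating training epoch.

    ``real_images`` is (M, H, W, 3) in [0, 1] with per-image class labels.
    The discriminator takes two separate updates — a half batch of real
    images (target 1), then a half batch of generated images (target 0) —
    followed by one generator update through the frozen discriminator with
    the fake targets reversed to 1.
    """
    if batch_size % 2:
        raise ValueError("batch_size must be even")
    if len(real_images) == 0:
        raise ValueError("empty real data source")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    gen, disc = bundle.generator, bundle.discriminator
    cfg = gen.config
    half = batch_size // 2
    nchw = np.transpose(np.asarray(real_images, dtype=np.float64), (0, 3, 1, 2))

    # --- discriminator, real half (target 1) ---
    idx = rng.choice(len(nchw), size=half, replace=len(nchw) < half)
    d_real = disc.forward(Tensor(nchw[idx]), real_labels[idx], rng=rng)
    loss_real_t = _bce(d_real, 1.0)
    disc.zero_grad()
    gen.zero_grad()
    loss_real_t.backward()
    bundle.opt_d.step()
    d_acc_real = float(np.mean(d_real.data > 0.5))
    d_loss_real = float(loss_real_t.data)

    # --- discriminator, fake half (target 0) ---
    z = rng.standard_normal((half, cfg.latent_dim))
    fake_labels = rng.integers(0, cfg.n_classes, size=half)
    fake = gen.generate(z, fake_labels)  # detached: generator held constant
    d_fake = disc.forward(Tensor(np.transpose(fake, (0, 3, 1, 2))),
                          fake_labels, rng=rng)
    loss_fake_t = _bce(d_fake, 0.0)
    disc.zero_grad()
    loss_fake_t.backward()
    bundle.opt_d.step()
    d_acc_fake = float(np.mean(d_fake.data <= 0.5))
    d_loss_fake = float(loss_fake_t.data)

    # --- generator through the frozen discriminator (reversed labels) ---
    z = rng.standard_normal((batch_size, cfg.latent_dim))
    g_labels = rng.integers(0, cfg.n_classes, size=batch_size)
    g_out = gen.forward(Tensor(z), g_labels)
    d_on_fake = disc.forward(g_out, g_labels, rng=rng)
    g_loss_t = _bce(d_on_fake, 1.0)
    gen.zero_grad()
    disc.zero_grad()
    g_loss_t.backward()
    bundle.opt_g.step()          # discriminator weights frozen: never stepped
    disc.zero_grad()

    return GanLossRecord(epoch=epoch, g_loss=float(g_loss_t.data),
                         d_loss_real=d_loss_real, d_loss_fake=d_loss_fake,
                         d_acc_real=d_acc_real, d_acc_fake=d_acc_fake)


def train_gan(bundle: GanBundle, real_images: np.ndarray,
              real_labels: np.ndarray, epochs: int, batch_size: int = 32,
              seed: int = 0) -> list[GanLossRecord]:
    rng = np.random.default_rng(seed)
    return [train_epoch(bundle, real_images, real_labels, epoch=e,
                        batch_size=batch_size, rng=rng)
            for e in range(epochs)]


def generate_batch(bundle: GanBundle, labels, rng_seed: int = 0) -> np.ndarray:
    """Synthesize one (n, H, W, 3) image per label (provenance: fake)."""
    labels = np.asarray(labels, dtype=np.intp)
    cfg = bundle.generator.config
    if labels.size and (labels.min() < 0 or labels.max() >= cfg.n_classes):
        raise ValueError("labels must be in [0, n_classes)")
    rng = np.random.default_rng(rng_seed)
    z = rng.standard_normal((len(labels), cfg.latent_dim))
    return bundle.generator.generate(z, labels)


def interpolate_black_pixels(image: np.ndarray, threshold: float = 0.1
                             ) -> np.ndarray:
    """Replace near-black pixels by the median of their non-black neighbors.

    A pixel is near-black when every channel is <= ``threshold`` (the
    normalized [0, 0.1] band by default).  Each pass replaces such pixels by
    the per-channel median over non-black pixels in the 3x3 window; passes
    repeat until no near-black pixel remains or a pass changes nothing.
    Pixels above threshold are never altered.
    """
    img = np.asarray(image, dtype=np.float64).copy()
    h, w = img.shape[:2]
    while True:
        black = np.all(img <= threshold, axis=-1)
        if not black.any():
            return img
        if black.all():
            warnings.warn("fully black image: no valid neighbors to "
                          "interpolate from", stacklevel=2)
            return img
        changed = False
        new = img.copy()
        ys, xs = np.nonzero(black)
        for y, x in zip(ys, xs):
            y0, y1 = max(y - 1, 0), min(y + 2, h)
            x0, x1 = max(x - 1, 0), min(x + 2, w)
            window = img[y0:y1, x0:x1].reshape(-1, img.shape[-1])
            valid = window[~np.all(window <= threshold, axis=-1)]
            if len(valid):
                new[y, x] = np.median(valid, axis=0)
                changed = True
        if not changed:
            return new
        img = new
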