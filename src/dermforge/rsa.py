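"""Representation similarity analysis between real and synthesized images.

Each image is converted to luminance grayscale, bilinearly resized to
200x200 and flattened row-major to a 40,000-dim vector.  The representation
similarity matrix (RSM) is the full pairwise Pearson correlation matrix over
30 sampled real plus 30 sampled fake vectors (real block first), so entries
lie in [-1, 1] with a unit diagonal.  Covariances use the population (1/D)
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.color import rgb2gray
from skimage.transform import resize

__all__ = ["RSA_SIDE", "RSA_DIM", "RSM", "project_image", "pearson",
           "build_rsm", "save_rsm", "plot_rsm"]

RSA_SIDE = 200
RSA_DIM = RSA_SIDE * RSA_SIDE  # 40,000


def project_image(image: np.ndarray) -> np.ndarray:
    """Project an image to a 40,000-dim grayscale vector.

    RGB images are reduced to luminance; anything not already 200x200 is
    bilinearly resized.  A 200x200 grayscale input passes through unchanged.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 3:
        img = rgb2gray(img)
    if img.shape != (RSA_SIDE, RSA_SIDE):
        img = resize(img, (RSA_SIDE, RSA_SIDE), order=1, mode="reflect",
                     anti_aliasing=False, preserve_range=True)
    return img.reshape(RSA_DIM)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation from population covariances.

    ``C_xy = (1/D) * sum((x_i - mean(x)) * (y_i - mean(y)))`` and
    ``rho = C_xy / sqrt(C_xx * C_yy)``.  A zero-variance input makes the
    coefficient undefined; NaN is returned as the flagged missing value.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    xc = x - x.mean()
    yc = y - y.mean()
    d = x.size
    cxx = float(xc @ xc) / d
    cyy = float(yc @ yc) / d
    if cxx == 0.0 or cyy == 0.0:
        return float("nan")
    cxy = float(xc @ yc) / d
    return float(np.clip(cxy / np.sqrt(cxx * cyy), -1.0, 1.0))


@dataclass
class RSM:
    """Symmetric correlation matrix; rows ordered real block then fake block."""

    matrix: np.ndarray
    n_real: int
    n_fake: int

    def block_means(self) -> dict:
        """Mean off-diagonal correlation per block (soft realism readout)."""
        m, nr = self.matrix, self.n_real
        off = ~np.eye(len(m), dtype=bool)
        rr = m[:nr, :nr][off[:nr, :nr]]
        ff = m[nr:, nr:][off[nr:, nr:]]
        rf = m[:nr, nr:].ravel()
        return {"real_real": float(rr.mean()), "fake_fake": float(ff.mean()),
                "real_fake": float(rf.mean())}


def build_rsm(real_images, fake_images, n_per_class: int = 30,
              seed: int = 0) -> RSM:
    """Sample, project, and correlate real vs fake image sets.

    ``n_per_class`` images are drawn without replacement from each pool with
    the given seed; the returned matrix is (2n x 2n) with the real block
    first.
    """
    real_images = list(real_images)
    fake_images = list(fake_images)
    if len(real_images) < n_per_class or len(fake_images) < n_per_class:
        raise ValueError(
            f"need at least {n_per_class} images in each pool "
            f"(got {len(real_images)} real, {len(fake_images)} fake)")
    rng = np.random.default_rng(seed)
    ri = rng.choice(len(real_images), size=n_per_class, replace=False)
    fi = rng.choice(len(fake_images), size=n_per_class, replace=False)
    vectors = np.stack(
        [project_image(real_images[i]) for i in ri]
        + [project_image(fake_images[i]) for i in fi])

    centered = vectors - vectors.mean(axis=1, keepdims=True)
    cov = (centered @ centered.T) / vectors.shape[1]
    sd = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = cov / np.outer(sd, sd)
    matrix = np.clip(matrix, -1.0, 1.0)
    np.fill_diagonal(matrix, 1.0)
    return RSM(matrix=matrix, n_real=n_per_class, n_fake=n_per_class)


def save_rsm(rsm: RSM, path: str | Path):
    labels = ([f"real_{i}" for i in range(rsm.n_real)]
              + [f"fake_{i}" for i in range(rsm.n_fake)])
    pd.DataFrame(rsm.matrix, index=labels, columns=labels).to_csv(path)


def plot_rsm(rsm: RSM, path: str | Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(rsm.matrix, vmin=-1, vmax=1, cmap="viridis")
    ax.axhline(rsm.n_real - 0.5, color="w", lw=0.8)
    ax.axvline(rsm.n_real - 0.5, color="w", lw=0.8)
    ax.set_title("Representation similarity (real | fake)")
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.savefig(path, dpi=120)
    plt.close(fig)
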