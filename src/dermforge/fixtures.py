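"""Procedural dermoscopy-like fixture images.

Real dermoscopic corpora cannot ship with the package, so every downstream
stage (GAN, similarity analysis, detector) is exercised on procedurally
generated stand-ins: an elliptical lesion with a class-specific color drawn
on a uniform skin-tone background, optionally occluded by dark hair-like
strokes.  A controllable low-amplitude sinusoidal grid stands in for the
spatial fingerprint a generative model leaves behind, giving the deepfake
detector a learnable real-vs-fake signal.

Six lesion categories mirror the benign/malignant dermoscopy classes
AKIEC, BKL, NEVI, VASC, BCC and MEL; each maps to a fixed, well-separated
RGB centroid with a small per-image jitter so classes stay learnable at
tiny sample sizes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "CLASS_NAMES", "CLASS_PALETTE", "LesionSpec", "CorpusManifest",
    "generate_lesion", "ellipse_mask", "inject_fake_artifact", "build_corpus",
    "ARTIFACT_PERIOD", "ARTIFACT_AMPLITUDE",
]

CLASS_NAMES = ("AKIEC", "BKL", "NEVI", "VASC", "BCC", "MEL")

# Fixed RGB centroids, pairwise separated by >= 0.15 in at least one channel.
CLASS_PALETTE = np.array([
    [0.85, 0.45, 0.35],   # AKIEC  red-brown scale
    [0.60, 0.40, 0.20],   # BKL    tan keratosis
    [0.35, 0.22, 0.12],   # NEVI   dark brown
    [0.75, 0.25, 0.50],   # VASC   violaceous red
    [0.95, 0.50, 0.55],   # BCC    pearly pink
    [0.15, 0.12, 0.20],   # MEL    blue-black
])

COLOR_JITTER = 0.05        # per-channel uniform jitter around the centroid
ARTIFACT_PERIOD = 8        # pixels, the injected grid period
ARTIFACT_AMPLITUDE = 0.05  # default injected amplitude


@dataclass(frozen=True)
class LesionSpec:
    """Deterministic recipe for one fixture image."""

    class_id: int
    lesion_axes: tuple[float, float]
    lesion_color: tuple[float, float, float]
    background_tone: tuple[float, float, float]
    hair_count: int
    seed: int

    def __post_init__(self):
        if not 0 <= self.class_id <= 5:
            raise ValueError(f"class_id must be in [0, 5], got {self.class_id}")
        if self.hair_count < 0:
            raise ValueError("hair_count must be non-negative")

    @classmethod
    def random(cls, class_id: int, seed: int, size: int = 128,
               hair_count: int | None = None) -> "LesionSpec":
        """Draw a jittered spec for ``class_id``, deterministic in ``seed``."""
        if not 0 <= class_id <= 5:
            raise ValueError(f"class_id must be in [0, 5], got {class_id}")
        rng = np.random.default_rng([class_id, seed])
        color = CLASS_PALETTE[class_id] + rng.uniform(
            -COLOR_JITTER, COLOR_JITTER, size=3)
        tone = np.array([0.87, 0.72, 0.62]) + rng.uniform(-0.03, 0.03, size=3)
        axes = rng.uniform(0.22, 0.36, size=2) * size
        if hair_count is None:
            hair_count = int(rng.integers(0, 4))
        return cls(
            class_id=class_id,
            lesion_axes=(float(axes[0]), float(axes[1])),
            lesion_color=tuple(np.clip(color, 0.0, 1.0)),
            background_tone=tuple(np.clip(tone, 0.0, 1.0)),
            hair_count=hair_count,
            seed=seed,
        )


def _geometry(spec: LesionSpec, size: int):
    """Ellipse center/angle shared by the renderer and the exported mask."""
    rng = np.random.default_rng([spec.class_id, spec.seed, 7])
    cy, cx = size / 2 + rng.uniform(-0.08, 0.08, size=2) * size
    angle = rng.uniform(0.0, np.pi)
    return cy, cx, angle


def _ellipse_field(spec: LesionSpec, size: int) -> np.ndarray:
    """Normalized squared elliptical radius (1.0 on the lesion boundary)."""
    cy, cx, angle = _geometry(spec, size)
    a, b = spec.lesion_axes
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    return (u / a) ** 2 + (v / b) ** 2


def ellipse_mask(spec: LesionSpec, size: int) -> np.ndarray:
    """Boolean mask of the lesion ellipse (the region the renderer touches)."""
    return _ellipse_field(spec, size) <= 1.0


def generate_lesion(spec: LesionSpec, size: int = 128) -> np.ndarray:
    """Render one (size, size, 3) float image in [0, 1].

    The background is a uniform skin tone; all lesion pixels (including the
    feathered rim) lie strictly inside :func:`ellipse_mask`; ``hair_count``
    dark curvilinear strokes are overlaid on top.
    """
    if size < 16:
        raise ValueError(f"size must be >= 16, got {size}")
    rng = np.random.default_rng([spec.class_id, spec.seed, 13])
    img = np.ones((size, size, 3)) * np.asarray(spec.background_tone)

    field = _ellipse_field(spec, size)
    # feather the last 15% of the radius, entirely inside the ellipse
    alpha = np.clip((1.0 - field) / 0.15, 0.0, 1.0)
    inside = field <= 1.0
    alpha[~inside] = 0.0

    # mild radial texture so lesions are not flat discs
    texture = 1.0 - 0.15 * np.clip(field, 0.0, 1.0)
    lesion = np.asarray(spec.lesion_color)[None, None, :] * texture[..., None]
    img = img * (1.0 - alpha[..., None]) + lesion * alpha[..., None]

    for _ in range(spec.hair_count):
        _draw_hair(img, rng)
    return np.clip(img, 0.0, 1.0)


def _draw_hair(img: np.ndarray, rng: np.random.Generator):
    """Overlay one dark quadratic-Bezier stroke."""
    size = img.shape[0]
    p0 = rng.uniform(0, size, size=2)
    p1 = rng.uniform(0, size, size=2)
    p2 = rng.uniform(0, size, size=2)
    t = np.linspace(0.0, 1.0, 4 * size)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2
    rr = np.clip(pts[:, 0].astype(int), 0, size - 1)
    cc = np.clip(pts[:, 1].astype(int), 0, size - 1)
    shade = rng.uniform(0.04, 0.12)
    img[rr, cc] = [shade, shade * 0.85, shade * 0.7]


def inject_fake_artifact(image: np.ndarray, amplitude: float = ARTIFACT_AMPLITUDE,
                         period: int = ARTIFACT_PERIOD) -> np.ndarray:
    """Add a low-amplitude 2-D sinusoidal grid (a synthetic GAN fingerprint).

    The pattern is ``amplitude * sin(2*pi*x/period) * sin(2*pi*y/period)``,
    identical in all channels, clipped back to [0, 1].  Mean absolute pixel
    change is bounded by ``amplitude``.
    """
    if not 0.0 < amplitude <= 0.2:
        raise ValueError(f"amplitude must be in (0, 0.2], got {amplitude}")
    h, w = image.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    grid = amplitude * np.sin(2 * np.pi * xx / period) * np.sin(2 * np.pi * yy / period)
    return np.clip(image + grid[..., None], 0.0, 1.0)


@dataclass
class CorpusManifest:
    """Table of (path, class_id, provenance, split) rows plus its root dir."""

    frame: pd.DataFrame
    root: Path

    COLUMNS = ("path", "class_id", "provenance", "split")

    def __len__(self):
        return len(self.frame)

    def subset(self, split: str | None = None,
               provenance: str | None = None) -> pd.DataFrame:
        df = self.frame
        if split is not None:
            df = df[df["split"] == split]
        if provenance is not None:
            df = df[df["provenance"] == provenance]
        return df.reset_index(drop=True)

    def load_images(self, rows: pd.DataFrame | None = None) -> np.ndarray:
        """Read PNGs back as a (n, H, W, 3) float array in [0, 1]."""
        df = self.frame if rows is None else rows
        imgs = [iio.imread(self.root / p).astype(np.float64) / 255.0
                for p in df["path"]]
        return np.stack(imgs)

    def save(self, path: Path):
        self.frame.to_csv(path, index=False)

    @classmethod
    def read(cls, path: Path) -> "CorpusManifest":
        frame = pd.read_csv(path)
        missing = set(cls.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        return cls(frame=frame, root=Path(path).parent)


def build_corpus(n_per_class: int, fake_fraction: float, out_dir: str | Path,
                 seed: int, size: int = 128, train_fraction: float = 0.75,
                 ) -> CorpusManifest:
    """Write a labeled real/fake PNG corpus plus a CSV manifest.

    Per class, ``round(fake_fraction * n_per_class)`` images carry the
    injected artifact and are flagged ``fake``.  The train:test split is
    75:25, stratified within each (class, provenance) group.  Fixed
    ``seed`` gives a bit-identical corpus.
    """
    if n_per_class < 4:
        raise ValueError("n_per_class must be >= 4")
    if not 0.0 <= fake_fraction <= 1.0:
        raise ValueError("fake_fraction must be in [0, 1]")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        if not os.access(out_dir, os.W_OK):
            raise PermissionError(out_dir)
    except OSError as exc:
        raise IOError(f"cannot write to {out_dir}") from exc

    rows = []
    n_fake = int(round(fake_fraction * n_per_class))
    for class_id in range(6):
        for i in range(n_per_class):
            img_seed = seed * 1_000_003 + class_id * 10_007 + i
            spec = LesionSpec.random(class_id, img_seed, size=size)
            img = generate_lesion(spec, size=size)
            fake = i < n_fake
            if fake:
                img = inject_fake_artifact(img)
            name = f"img_c{class_id}_{i:04d}_{'fake' if fake else 'real'}.png"
            iio.imwrite(out_dir / name,
                        (np.round(img * 255.0)).astype(np.uint8))
            rows.append({"path": name, "class_id": class_id,
                         "provenance": "fake" if fake else "real"})

    frame = pd.DataFrame(rows)
    rng = np.random.default_rng(seed)
    frame["split"] = "train"
    for (_, _), grp in frame.groupby(["class_id", "provenance"]):
        idx = grp.index.to_numpy()
        rng.shuffle(idx)
        n_test = int(round((1.0 - train_fraction) * len(idx)))
        frame.loc[idx[:n_test], "split"] = "test"
    frame = frame[list(CorpusManifest.COLUMNS)]
    manifest = CorpusManifest(frame=frame, root=out_dir)
    manifest.save(out_dir / "manifest.csv")
    return manifest
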