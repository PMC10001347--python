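"""End-to-end plumbing: fixtures -> GAN -> RSA -> detector -> evaluation.

Every stage writes its artifacts under the run directory and reads its
inputs from the artifacts of upstream stages, failing with an explicit
dependency error when one is missing.  A run log records the configuration
hash and per-stage seeds so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import gan as gan_mod
from . import metrics as metrics_mod
from . import rsa as rsa_mod
from . import vit as vit_mod
from .config import RunConfig
from .fixtures import CorpusManifest, build_corpus

__all__ = ["StageDependencyError", "run_pipeline"]


class StageDependencyError(RuntimeError):
    """An upstream artifact required by a stage is missing."""


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise StageDependencyError(
            f"stage '{stage}' needs {path.name}, produced by stage "
            f"'{produced_by}' — run it first")
    return path


def _load_manifest(run_dir: Path, stage: str) -> CorpusManifest:
    return CorpusManifest.read(
        _require(run_dir / "corpus" / "manifest.csv", stage, "fixtures"))


def _save_gan(bundle: gan_mod.GanBundle, path: Path):
    cfg = bundle.generator.config
    arrays = {f"g_{k}": v for k, v in bundle.generator.state_dict().items()}
    arrays |= {f"d_{k}": v for k, v in bundle.discriminator.state_dict().items()}
    arrays["config"] = np.frombuffer(
        json.dumps(cfg.__dict__).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def _load_gan(path: Path) -> gan_mod.GanBundle:
    with np.load(path) as data:
        cfg = gan_mod.GanConfig(**json.loads(bytes(data["config"]).decode()))
        bundle = gan_mod.GanBundle.build(cfg)
        bundle.generator.load_state_dict(
            {k[2:]: data[k] for k in data.files if k.startswith("g_")})
        bundle.discriminator.load_state_dict(
            {k[2:]: data[k] for k in data.files if k.startswith("d_")})
    return bundle


def _sample_grid(bundle: gan_mod.GanBundle, path: Path, seed: int):
    """One generated image per class, tiled into a row."""
    imgs = gan_mod.generate_batch(bundle, np.arange(6), rng_seed=seed)
    grid = np.concatenate(list(imgs), axis=1)
    iio.imwrite(path, (np.round(grid * 255)).astype(np.uint8))


def run_pipeline(config: RunConfig, stages=None) -> Path:
    """Execute the requested stages in canonical order; returns the run dir."""
    run_dir = Path(config.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages or config.stages)
    log = {"config_digest": config.digest(), "stages": {}, "seeds": {
        s: getattr(config, s).seed for s in
        ("fixtures", "gan", "rsa", "vit", "eval")}}

    for stage in ("fixtures", "gan", "rsa", "vit", "eval"):
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        globals()[f"_stage_{stage}"](config, run_dir)
        log["stages"][stage] = round(time.perf_counter() - t0, 3)

    (run_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return run_dir


def _stage_fixtures(config: RunConfig, run_dir: Path):
    fc = config.fixtures
    build_corpus(n_per_class=fc.n_per_class, fake_fraction=fc.fake_fraction,
                 out_dir=run_dir / "corpus", seed=fc.seed, size=fc.size)


def _stage_gan(config: RunConfig, run_dir: Path):
    gc = config.gan
    manifest = _load_manifest(run_dir, "gan")
    real = manifest.subset(provenance="real")
    images = manifest.load_images(real)
    if images.shape[1] != gc.image_size:
        from skimage.transform import resize
        images = np.stack([resize(im, (gc.image_size, gc.image_size), order=1,
                                  anti_aliasing=False, preserve_range=True)
                           for im in images])
    labels = real["class_id"].to_numpy()

    cfg = gan_mod.GanConfig(image_size=gc.image_size, latent_dim=gc.latent_dim,
                            base_filters=gc.base_filters)
    bundle = gan_mod.GanBundle.build(cfg, seed=gc.seed)
    records = []
    rng = np.random.default_rng(gc.seed)
    grids = run_dir / "gan_samples"
    grids.mkdir(exist_ok=True)
    for epoch in range(gc.epochs):
        records.append(gan_mod.train_epoch(bundle, images, labels,
                                           epoch=epoch,
                                           batch_size=gc.batch_size, rng=rng))
        if (epoch + 1) % gc.sample_every == 0 or epoch + 1 == gc.epochs:
            _sample_grid(bundle, grids / f"epoch_{epoch + 1:05d}.png",
                         seed=gc.seed)
    pd.DataFrame([r.__dict__ for r in records])[
        list(gan_mod.GanLossRecord.FIELDS)].to_csv(
        run_dir / "gan_losses.csv", index=False)
    _save_gan(bundle, run_dir / "gan_checkpoint.npz")


def _stage_rsa(config: RunConfig, run_dir: Path):
    rc = config.rsa
    manifest = _load_manifest(run_dir, "rsa")
    real_imgs = list(manifest.load_images(manifest.subset(provenance="real")))
    if rc.use_gan_fakes:
        ckpt = _require(run_dir / "gan_checkpoint.npz", "rsa", "gan")
        bundle = _load_gan(ckpt)
        labels = np.arange(rc.n_per_class) % 6
        fake_imgs = list(gan_mod.generate_batch(bundle, labels,
                                                rng_seed=rc.seed))
        fake_imgs = [gan_mod.interpolate_black_pixels(im) for im in fake_imgs]
    else:
        fake_imgs = list(manifest.load_images(
            manifest.subset(provenance="fake")))
    rsm = rsa_mod.build_rsm(real_imgs, fake_imgs, n_per_class=rc.n_per_class,
                            seed=rc.seed)
    rsa_mod.save_rsm(rsm, run_dir / "rsm.csv")
    rsa_mod.plot_rsm(rsm, run_dir / "rsm.png")
    (run_dir / "rsm_blocks.json").write_text(
        json.dumps(rsm.block_means(), indent=2))


def _stage_vit(config: RunConfig, run_dir: Path):
    vc = config.vit
    manifest = _load_manifest(run_dir, "vit")
    model = vit_mod.build_vit(vc.variant, seed=vc.seed,
                              embed_dim=vc.embed_dim, depth=vc.depth,
                              mlp_dims=tuple(vc.mlp_dims))
    det_cfg = vit_mod.DetectorConfig(epochs=vc.epochs,
                                     batch_size=vc.batch_size,
                                     augment=vc.augment, seed=vc.seed)
    model, history = vit_mod.train_detector(model, manifest, det_cfg)
    history.to_csv(run_dir / "vit_history.csv", index=False)
    arrays = model.state_dict()
    arrays["norm_mean"] = model.norm_mean
    arrays["norm_std"] = model.norm_std
    np.savez(run_dir / "vit_checkpoint.npz", **arrays)
    (run_dir / "vit_meta.json").write_text(json.dumps({
        "variant": model.variant.name, "embed_dim": vc.embed_dim,
        "depth": vc.depth, "mlp_dims": list(vc.mlp_dims),
        "param_count": model.param_count()}, indent=2))


def _stage_eval(config: RunConfig, run_dir: Path):
    vc = config.vit
    manifest = _load_manifest(run_dir, "eval")
    meta_path = _require(run_dir / "vit_meta.json", "eval", "vit")
    meta = json.loads(meta_path.read_text())
    model = vit_mod.build_vit(meta["variant"], embed_dim=meta["embed_dim"],
                              depth=meta["depth"],
                              mlp_dims=tuple(meta["mlp_dims"]), seed=vc.seed)
    with np.load(_require(run_dir / "vit_checkpoint.npz", "eval", "vit")) as d:
        model.norm_mean = d["norm_mean"]
        model.norm_std = d["norm_std"]
        model.load_state_dict({k: d[k] for k in d.files
                               if k not in ("norm_mean", "norm_std")})
    test = manifest.subset(split="test")
    images = manifest.load_images(test)
    size = model.variant.image_size
    if images.shape[1] != size:
        from skimage.transform import resize
        images = np.stack([resize(im, (size, size), order=1,
                                  anti_aliasing=False, preserve_range=True)
                           for im in images])
    probs, pred = vit_mod.predict(model, images)
    truth = (test["provenance"] == "real").to_numpy().astype(int)
    pd.DataFrame({"path": test["path"], "truth": truth, "pred": pred,
                  "p_real": probs[:, 1]}).to_csv(
        run_dir / "predictions.csv", index=False)
    cm = metrics_mod.confusion(truth, pred)
    curves = metrics_mod.roc_pr_auc(truth, probs[:, 1])
    metrics_mod.write_report(cm, curves, run_dir / "report.json")
    metrics_mod.plot_curves(curves, run_dir / "plots")
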