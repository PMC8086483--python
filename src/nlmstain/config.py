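"""YAML pipeline configuration and the stage orchestrator.

A single top-level seed is fanned out deterministically per stage; every run
writes a ``manifest.json`` (config snapshot, per-stage seeds and timings,
output checksums) next to its artifacts, and a resumed run skips stages the
manifest records as complete when their outputs still exist.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import replace
from pathlib import Path
from typing import List, Literal, Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "stage_seed"]


class PhantomStage(BaseModel):
    image_size: Tuple[int, int] = (256, 256)
    crypt_count: int = 5
    noise_sigma: float = 4.0
    n_pairs: int = 64
    n_val: int = 8
    patch_size: int = 64


class TrainStage(BaseModel):
    mode: Literal["pix2pix", "cyclegan"] = "pix2pix"
    epochs: int = 5
    checkpoint_interval: int = 5
    reduced: bool = True
    lambda_mae: float = 10.0
    selection_metric: Literal["ssim", "css", "mse"] = "ssim"


class StainStage(BaseModel):
    correct_seams: bool = True
    contrast_factor: Optional[float] = None


class EvaluateStage(BaseModel):
    ssim_mode: Literal["local", "global"] = "local"
    css_threshold: float = 0.5
    exclude_background: bool = True


class PipelineConfig(BaseModel):
    seed: int = 0
    out_dir: str = "nlmstain_run"
    stages: List[Literal["phantom", "train", "stain", "evaluate"]] = Field(
        default_factory=lambda: ["phantom", "train", "stain", "evaluate"]
    )
    phantom: PhantomStage = Field(default_factory=PhantomStage)
    train: TrainStage = Field(default_factory=TrainStage)
    stain: StainStage = Field(default_factory=StainStage)
    evaluate: EvaluateStage = Field(default_factory=EvaluateStage)


def load_config(path: Path) -> PipelineConfig:
    try:
        return PipelineConfig.model_validate(yaml.safe_load(Path(path).read_text()) or {})
    except ValidationError as err:
        raise ValueError(f"invalid pipeline config {path}:\n{err}") from None


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, resume: bool = False) -> Path:
    """Execute the requested stages in order; returns the output directory."""
    from . import __version__
    from .evaluation import EvalConfig, evaluate_dataset
    from .inference import adjust_contrast, stain_image
    from .io import read_image, write_image
    from .models import UNetGenerator
    from .phantom import PhantomParams, generate_phantom_pair, generate_patch_dataset
    from .preprocessing import invert_contrast
    from .training import (
        Checkpoint,
        TrainConfig,
        make_supervised_patches,
        select_checkpoint,
        train_cyclegan,
        train_pix2pix,
    )
    from .types import MultimodalImage

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if (resume and manifest_path.exists()) else {
        "config": config.model_dump(),
        "version": __version__,
        "stages": {},
    }

    def done(stage: str, outputs: List[Path]) -> bool:
        entry = manifest["stages"].get(stage)
        return bool(entry and entry.get("complete") and all(Path(p).exists() for p in entry.get("outputs", [])))

    def finish(stage: str, t0: float, outputs: List[Path]) -> None:
        manifest["stages"][stage] = {
            "complete": True,
            "seed": stage_seed(config.seed, stage),
            "seconds": round(time.time() - t0, 3),
            "outputs": [str(p) for p in outputs],
            "checksums": {p.name: _checksum(p) for p in outputs if p.is_file()},
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))

    ps = config.phantom
    side = min(ps.image_size)
    params = PhantomParams(
        image_size=tuple(ps.image_size),
        crypt_count=ps.crypt_count,
        crypt_radius_range=(side / 16, side / 8),
        noise_sigma=ps.noise_sigma,
        seed=stage_seed(config.seed, "phantom"),
    )
    test_nlm_path, test_he_path = out / "test_nlm.tif", out / "test_he.tif"
    ckpt_dir = out / "checkpoints"
    stained_path = out / "stained.png"
    report_path = out / "report.csv"

    if "phantom" in config.stages and not done("phantom", [test_nlm_path, test_he_path]):
        t0 = time.time()
        nlm, he, _, _ = generate_phantom_pair(replace(params, seed=params.seed + 7))
        write_image(test_nlm_path, nlm.pixels)
        write_image(test_he_path, he.pixels)
        finish("phantom", t0, [test_nlm_path, test_he_path])

    selected: Optional[Checkpoint] = None
    if "train" in config.stages and not done("train", [ckpt_dir / "selected.npz"]):
        t0 = time.time()
        ts = config.train
        tcfg_kw = dict(
            epochs=ts.epochs,
            checkpoint_interval=ts.checkpoint_interval,
            lambda_mae=ts.lambda_mae,
            seed=stage_seed(config.seed, "train"),
        )
        tcfg = TrainConfig.reduced(**tcfg_kw) if ts.reduced else TrainConfig(**tcfg_kw)
        pairs = generate_patch_dataset(params, ps.n_pairs + ps.n_val, patch_size=ps.patch_size, paired=True)
        train_pairs = make_supervised_patches(pairs[: ps.n_pairs])
        val_pairs = make_supervised_patches(pairs[ps.n_pairs :])
        if ts.mode == "pix2pix":
            result = train_pix2pix(train_pairs, tcfg, out_dir=ckpt_dir)
        else:
            nlm_pool, he_pool = generate_patch_dataset(params, ps.n_pairs, patch_size=ps.patch_size, paired=False)
            xs = [p[0] for p in make_supervised_patches([(a, a) for a in nlm_pool])]
            ys = [p[1] for p in make_supervised_patches([(b, b) for b in he_pool])]
            result = train_cyclegan(xs, ys, tcfg, out_dir=ckpt_dir)
        selected = select_checkpoint(result.checkpoints, val_pairs, metric=ts.selection_metric)
        selected.save(ckpt_dir / "selected.npz", seed=tcfg.seed)
        finish("train", t0, [ckpt_dir / "selected.npz"])

    if "stain" in config.stages and not done("stain", [stained_path]):
        t0 = time.time()
        ck = ckpt_dir / "selected.npz"
        if not ck.exists():
            raise FileNotFoundError(f"stain stage needs a trained checkpoint at {ck}")
        if selected is None:
            from .models import GeneratorSpecUNet

            state = dict(np.load(ck))
            spec = GeneratorSpecUNet.reduced() if config.train.reduced else GeneratorSpecUNet()
            gen = UNetGenerator(spec)
            gen.load_state_dict(state)
        else:
            gen = UNetGenerator(selected.spec)
            gen.load_state_dict(selected.state)
        nlm_px = read_image(test_nlm_path)
        inverted = MultimodalImage(invert_contrast(nlm_px))
        pred = stain_image(gen, inverted, patch_size=ps.patch_size, correct_seams=config.stain.correct_seams)
        px = pred.pixels
        if config.stain.contrast_factor:
            px = adjust_contrast(px, config.stain.contrast_factor)
        write_image(stained_path, px)
        finish("stain", t0, [stained_path])

    if "evaluate" in config.stages and not done("evaluate", [report_path]):
        t0 = time.time()
        pred = read_image(stained_path)
        ref = read_image(test_he_path)
        ecfg = EvalConfig(
            ssim_mode=config.evaluate.ssim_mode,
            css_threshold=config.evaluate.css_threshold,
            exclude_background=config.evaluate.exclude_background,
            background_tile=ps.patch_size,
        )
        evaluate_dataset([(pred, ref)], ecfg, names=["test"], csv_path=report_path)
        finish("evaluate", t0, [report_path])

    return out
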