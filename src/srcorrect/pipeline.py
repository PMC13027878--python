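"""End-to-end orchestration: scale presets, staged runs, and the full
simulate → reconstruct → train → evaluate experiment.

Two presets share one interface:

- ``desk``: a CPU-scale study (128×128 phantom grid, 0.2 mm pixels,
  32 sensors on a 14 mm ring, 2 MHz / 70% transducers, 512 samples at
  25 MHz, small encoder) whose radius sweep scales the reference geometry
  proportionally (ΔR/R = ±1.0/24.8 in 11 steps);
- ``full``: the full-scale geometry (768×768 grid at 40 µm, 256 sensors at
  24.8 mm, 5 MHz / 70%, 4500 samples at 50 MHz, radii 23.8–25.8 mm in
  0.2 mm steps, ResNet-50 encoder).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from srcorrect import dataset as dataset_mod
from srcorrect.das import ReconGrid, radius_grid
from srcorrect.dataset import (
    TrainingPair,
    build_dataset,
    pairs_by_phantom,
    split_dataset,
)
from srcorrect.metrics import MetricReport, evaluate_testset, model_corrector
from srcorrect.phantoms import FAMILIES, PhantomSpec, generate_phantom
from srcorrect.sdresnet import ModelConfig, SDResNet, build_model
from srcorrect.training import TrainConfig, inference_weights, train
from srcorrect.wave import Medium, SensorRing, save_sinogram

REFERENCE_RADIUS_MM = 24.8
REFERENCE_SWEEP_MM = (23.8, 25.8, 0.2)


@dataclass(frozen=True)
class RunConfig:
    """Master configuration: one seed propagates to every stage."""

    scale: str = "desk"
    seed: int = 0
    n_phantoms: int = 40
    # simulation
    canvas: int = 128
    dx: float = 2.0e-4
    ring_radius: float = 14.0e-3
    n_sensors: int = 32
    f0: float = 2.0e6
    frac_bw: float = 0.7
    fs: float = 25.0e6
    n_t: int = 512
    noise_db: float = -30.0
    # reconstruction
    recon_n: int = 128
    recon_dx: float = 1.4e-4
    # dataset / training
    split_ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    patch: int = 64
    batch_size: int = 8
    epochs: int = 24
    base_lr: float = 2e-3
    norm_scope: str = "image"
    encoder_variant: str = "small"
    placement_frac: float = 0.59

    def medium(self) -> Medium:
        return Medium()

    def ring(self) -> SensorRing:
        return SensorRing(n_sensors=self.n_sensors, radius=self.ring_radius,
                          f0=self.f0, frac_bw=self.frac_bw)

    def grid(self) -> ReconGrid:
        return ReconGrid(nx=self.recon_n, ny=self.recon_n,
                         dx=self.recon_dx, dy=self.recon_dx)

    def radii(self) -> np.ndarray:
        lo, hi, step = REFERENCE_SWEEP_MM
        scale = self.ring_radius / (REFERENCE_RADIUS_MM * 1e-3)
        return radius_grid(lo * 1e-3 * scale, hi * 1e-3 * scale, step * 1e-3 * scale)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "split_ratios" in raw:
            raw["split_ratios"] = tuple(raw["split_ratios"])
        return cls(**raw)


def desk_config(**overrides) -> RunConfig:
    return RunConfig(**overrides)


def full_config(**overrides) -> RunConfig:
    base = dict(
        scale="full", canvas=768, dx=4.0e-5, ring_radius=24.8e-3, n_sensors=256,
        f0=5.0e6, frac_bw=0.7, fs=50.0e6, n_t=4500, recon_n=512, recon_dx=4.0e-5,
        patch=224, encoder_variant="resnet50", n_phantoms=480, epochs=2000,
        base_lr=2e-4, norm_scope="patch",
    )
    base.update(overrides)
    return RunConfig(**base)


def phantom_specs(config: RunConfig) -> list[PhantomSpec]:
    """One spec per phantom, cycling the structure families, seeds derived
    from the master seed."""
    master = np.random.default_rng(config.seed)
    specs = []
    for k in range(config.n_phantoms):
        specs.append(PhantomSpec(
            family=FAMILIES[k % len(FAMILIES)],
            canvas=config.canvas,
            seed=int(master.integers(0, 2 ** 31)),
            placement_frac=config.placement_frac,
        ))
    return specs


def _log(log_file, stage: str, seed: int, t0: float, **extra) -> None:
    if log_file is None:
        return
    rec = {"stage": stage, "seed": seed, "wall_s": round(time.time() - t0, 3), **extra}
    with open(log_file, "a") as fh:
        fh.write(json.dumps(rec) + "\n")


def cmd_simulate(config: RunConfig, out_dir) -> list[Path]:
    """One HDF5 RF file per phantom plus a YAML manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    medium, ring = config.medium(), config.ring()
    paths = []
    from srcorrect.wave import apply_transducer_band, simulate_rf

    for k, spec in enumerate(phantom_specs(config)):
        p0 = generate_phantom(spec, dx=config.dx)
        sino = apply_transducer_band(simulate_rf(p0, medium, ring, config.n_t, config.fs),
                                     ring.f0, ring.frac_bw)
        path = out / f"rf_{k:04d}.h5"
        save_sinogram(path, sino, radius_true=ring.radius, c=medium.c, seed=spec.seed)
        paths.append(path)
    manifest = {"scale": config.scale, "seed": config.seed,
                "n_phantoms": config.n_phantoms, "fs": config.fs, "n_t": config.n_t,
                "radii_m": [float(r) for r in config.radii()],
                "files": [p.name for p in paths]}
    dataset_mod.write_manifest(out / "manifest.yaml", manifest)
    _log(out / "log.jsonl", "simulate", config.seed, t0, n_files=len(paths))
    return paths


def cmd_build_dataset(config: RunConfig, out_dir):
    """Build pairs from scratch and write per-split HDF5 files + CSV index."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    pairs = build_dataset(phantom_specs(config), config.medium(), config.ring(),
                          config.radii(), config.noise_db, config.seed,
                          grid=config.grid(), n_t=config.n_t, fs=config.fs)
    splits = split_dataset(config.n_phantoms, config.split_ratios, config.seed)
    named = {}
    for name, idx in zip(("train", "val", "test"), splits):
        subset = pairs_by_phantom(pairs, idx)
        dataset_mod.save_pairs(out / f"{name}.h5", subset)
        dataset_mod.write_index_csv(out / f"{name}_index.csv", subset)
        named[name] = subset
    _log(out / "log.jsonl", "build-dataset", config.seed, t0,
         sizes={k: len(v) for k, v in named.items()})
    return named


def cmd_train(config: RunConfig, splits: dict, out_dir):
    """Train the model on pre-built splits; persists checkpoints and history."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    model = build_model(ModelConfig(encoder_variant=config.encoder_variant,
                                    seed=config.seed))
    tcfg = TrainConfig(max_epochs=config.epochs, batch_size=config.batch_size,
                       patch=config.patch, seed=config.seed,
                       base_lr=config.base_lr, norm_scope=config.norm_scope)
    state, history = train(model, splits["train"], splits["val"], tcfg,
                           log_path=out / "history.csv")
    from srcorrect.sdresnet import save_checkpoint

    model.load_state_dict(inference_weights(state))
    save_checkpoint(out / "checkpoint_last.npz", model)
    if state.best_ema_weights is not None:
        model.load_state_dict(state.best_ema_weights)
        save_checkpoint(out / "checkpoint_best.npz", model)
    model.load_state_dict(inference_weights(state))
    _log(out / "log.jsonl", "train", config.seed, t0, epochs=len(history),
         best_epoch=state.best_epoch)
    return model, state, history


def cmd_eval(config: RunConfig, model: SDResNet, test_pairs: list[TrainingPair],
             out_dir) -> MetricReport:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report = evaluate_testset(model_corrector(model), test_pairs)
    report.to_csv(out / "metrics.csv")
    report.summary_json(out / "summary.json")
    _log(out / "log.jsonl", "eval", config.seed, t0, n_images=len(test_pairs) )
    return report


def run_end_to_end(config: RunConfig, out_dir=None):
    """Simulate, build, train and evaluate in one pass.

    Returns (report, aggregate-dict, model, splits)."""
    splits_pairs = cmd_build_dataset_in_memory(config)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
    model = build_model(ModelConfig(encoder_variant=config.encoder_variant,
                                    seed=config.seed))
    tcfg = TrainConfig(max_epochs=config.epochs, batch_size=config.batch_size,
                       patch=config.patch, seed=config.seed,
                       base_lr=config.base_lr, norm_scope=config.norm_scope)
    state, history = train(model, splits_pairs["train"], splits_pairs["val"], tcfg,
                           log_path=None if out_dir is None else Path(out_dir) / "history.csv")
    model.load_state_dict(inference_weights(state))
    report = evaluate_testset(model_corrector(model), splits_pairs["test"])
    agg = report.aggregate()
    if out_dir is not None:
        report.to_csv(Path(out_dir) / "metrics.csv")
        report.summary_json(Path(out_dir) / "summary.json")
    return report, agg, model, splits_pairs


def cmd_build_dataset_in_memory(config: RunConfig) -> dict[str, list[TrainingPair]]:
    """As :func:`cmd_build_dataset` but without touching disk."""
    pairs = build_dataset(phantom_specs(config), config.medium(), config.ring(),
                          config.radii(), config.noise_db, config.seed,
                          grid=config.grid(), n_t=config.n_t, fs=config.fs)
    splits = split_dataset(config.n_phantoms, config.split_ratios, config.seed)
    return {name: pairs_by_phantom(pairs, idx)
            for name, idx in zip(("train", "val", "test"), splits)}
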