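"""Paired degraded/ground-truth dataset construction and preprocessing.

For each phantom the RF data are simulated once; the noise-free
reconstruction at the true scanning radius is the ground truth (GT), and
one degraded image per sweep radius is reconstructed from noise-added RF.
Preprocessing follows the training recipe: a pairwise intensity rescaling
(the 0.5–99.5 percentile range of the GT defines a shared normalization
interval for both members), center cropping, random patch sampling, joint
horizontal/vertical flips, and replication of the grayscale input into
three identical channels.

Splitting is at the *phantom* level — every radius condition of a phantom
stays in one subset — which is the only reading consistent with a test set
of (number of test phantoms) × (number of radii) images.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace

import h5py
import numpy as np
import yaml

from srcorrect import das as das_mod
from srcorrect import wave as wave_mod
from srcorrect.das import DASConfig, ReconGrid
from srcorrect.errors import ConfigurationError, ShapeError
from srcorrect.phantoms import PhantomSpec, generate_phantom
from srcorrect.wave import Medium, SensorRing


@dataclass(frozen=True)
class TrainingPair:
    """Degraded/GT image pair plus scanning-radius metadata."""

    degraded: np.ndarray
    gt: np.ndarray
    phantom_id: str
    radius_used: float
    noise_seed: int

    def __post_init__(self) -> None:
        if self.degraded.shape != self.gt.shape:
            raise ShapeError("degraded and GT images must share a shape")


@dataclass(frozen=True)
class NormInterval:
    """Shared pairwise normalization interval from GT percentiles."""

    lo: float
    hi: float
    degenerate: bool = False


def build_dataset(
    phantom_specs: list[PhantomSpec],
    medium: Medium,
    ring: SensorRing,
    radii: np.ndarray,
    noise_db: float,
    seed: int,
    *,
    grid: ReconGrid,
    n_t: int,
    fs: float,
    c_assumed: float | None = None,
) -> list[TrainingPair]:
    """Simulate each phantom once and reconstruct the GT + one degraded
    image per sweep radius; deterministic under a fixed seed."""
    if len(radii) == 0:
        raise ConfigurationError("radius sweep is empty")
    c_assumed = medium.c if c_assumed is None else c_assumed
    master = np.random.default_rng(seed)
    pairs: list[TrainingPair] = []
    for idx, spec in enumerate(phantom_specs):
        p0 = generate_phantom(spec)
        sino = wave_mod.simulate_rf(p0, medium, ring, n_t, fs)
        sino = wave_mod.apply_transducer_band(sino, ring.f0, ring.frac_bw)
        gt = das_mod.das_reconstruct(
            sino, ring.angles, DASConfig(radius_assumed=ring.radius, c_assumed=c_assumed), grid)
        phantom_id = f"phantom_{idx:04d}"
        for radius in radii:
            noise_seed = int(master.integers(0, 2 ** 31))
            noisy = wave_mod.add_white_noise(sino, noise_db, noise_seed)
            degraded = das_mod.das_reconstruct(
                noisy, ring.angles,
                DASConfig(radius_assumed=float(radius), c_assumed=c_assumed), grid)
            pairs.append(TrainingPair(degraded=degraded, gt=gt, phantom_id=phantom_id,
                                      radius_used=float(radius), noise_seed=noise_seed))
    return pairs


def normalize_pair(pair: TrainingPair, lo_pct: float = 0.5, hi_pct: float = 99.5):
    """Map both members by x -> (x-lo)/(hi-lo) with lo/hi from GT percentiles,
    clipping to [0, 1].  A constant GT yields two zero images, flagged."""
    lo, hi = np.percentile(pair.gt, [lo_pct, hi_pct])
    if hi <= lo:
        zeros = np.zeros_like(pair.gt)
        return replace(pair, degraded=zeros.copy(), gt=zeros), NormInterval(float(lo), float(hi), True)

    def _map(img):
        return np.clip((img - lo) / (hi - lo), 0.0, 1.0)

    return (replace(pair, degraded=_map(pair.degraded), gt=_map(pair.gt)),
            NormInterval(float(lo), float(hi), False))


def center_crop(image: np.ndarray, size: int) -> np.ndarray:
    """Centered ``size`` × ``size`` window (e.g. 512 -> 400 keeps offset 56)."""
    h, w = image.shape
    if size > min(h, w):
        raise ConfigurationError(f"crop size {size} exceeds image {image.shape}")
    top, left = (h - size) // 2, (w - size) // 2
    return image[top:top + size, left:left + size]


def center_crop_pair(pair: TrainingPair, size: int) -> TrainingPair:
    return replace(pair, degraded=center_crop(pair.degraded, size),
                   gt=center_crop(pair.gt, size))


def sample_patch(pair: TrainingPair, patch: int, rng) -> TrainingPair:
    """The same uniformly random window applied to both members."""
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    h, w = pair.gt.shape
    if patch > min(h, w):
        raise ConfigurationError(f"patch {patch} exceeds image {pair.gt.shape}")
    top = int(gen.integers(0, h - patch + 1))
    left = int(gen.integers(0, w - patch + 1))
    return replace(pair, degraded=pair.degraded[top:top + patch, left:left + patch],
                   gt=pair.gt[top:top + patch, left:left + patch])


def augment_flip(pair: TrainingPair, rng) -> TrainingPair:
    """Joint horizontal/vertical flips, each axis with probability 0.5."""
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    degraded, gt = pair.degraded, pair.gt
    if gen.uniform() < 0.5:
        degraded, gt = degraded[:, ::-1], gt[:, ::-1]
    if gen.uniform() < 0.5:
        degraded, gt = degraded[::-1, :], gt[::-1, :]
    return replace(pair, degraded=degraded.copy(), gt=gt.copy())


def replicate_channels(patch: np.ndarray) -> np.ndarray:
    """Replicate a 2D grayscale patch into three identical channels (3, H, W)."""
    if patch.ndim != 2:
        raise ShapeError("expected a 2D patch")
    return np.repeat(patch[None, :, :], 3, axis=0)


def split_dataset(n_phantoms: int, ratios: tuple[float, float, float], seed: int):
    """Random phantom-level split; returns (train, val, test) index arrays."""
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigurationError("ratios must be positive and sum to 1")
    n_train = int(np.floor(n_phantoms * ratios[0]))
    n_val = int(np.floor(n_phantoms * ratios[1]))
    n_test = n_phantoms - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ConfigurationError(f"{n_phantoms} phantoms cannot fill three subsets")
    perm = np.random.default_rng(seed).permutation(n_phantoms)
    return perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]


def pairs_by_phantom(pairs: list[TrainingPair], indices) -> list[TrainingPair]:
    wanted = {f"phantom_{i:04d}" for i in np.asarray(indices).tolist()}
    return [p for p in pairs if p.phantom_id in wanted]


# ---------------------------------------------------------------------------
# persistence

def save_pairs(path, pairs: list[TrainingPair]) -> None:
    with h5py.File(path, "w") as fh:
        for k, pair in enumerate(pairs):
            grp = fh.create_group(f"pair_{k:05d}")
            grp.create_dataset("degraded", data=pair.degraded.astype(np.float32))
            grp.create_dataset("gt", data=pair.gt.astype(np.float32))
            grp.attrs["phantom_id"] = pair.phantom_id
            grp.attrs["radius_used"] = pair.radius_used
            grp.attrs["noise_seed"] = pair.noise_seed


def load_pairs(path) -> list[TrainingPair]:
    pairs = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh.keys()):
            grp = fh[key]
            pairs.append(TrainingPair(
                degraded=grp["degraded"][()].astype(np.float64),
                gt=grp["gt"][()].astype(np.float64),
                phantom_id=str(grp.attrs["phantom_id"]),
                radius_used=float(grp.attrs["radius_used"]),
                noise_seed=int(grp.attrs["noise_seed"]),
            ))
    return pairs


def write_index_csv(path, pairs: list[TrainingPair]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "phantom_id", "radius_used_m", "noise_seed"])
        for k, pair in enumerate(pairs):
            writer.writerow([k, pair.phantom_id, f"{pair.radius_used:.6e}", pair.noise_seed])


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh)
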