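"""Delay-and-sum (DAS) reconstruction parameterized by an assumed scanning radius.

DAS forms each pixel as the sum over channels of the RF signal evaluated at
that pixel's time of flight, t_i(Q) = |r_sensor,i − r_Q| / c, where the
sensor position is placed at the *assumed* radius.  When the assumed radius
differs from the true one by ΔR, a point target blurs into a ring of radius
≈ |ΔR| — the artifact this package corrects.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from srcorrect.errors import ConfigurationError, GeometryError, ShapeError
from srcorrect.wave import Sinogram


@dataclass(frozen=True)
class ReconGrid:
    """Square pixel grid centered on the ring center (the origin)."""

    nx: int
    ny: int
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        if self.dx <= 0 or self.dy <= 0:
            raise ConfigurationError("pixel sizes must be positive")

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel center coordinates (X, Y), each (ny, nx), in meters."""
        x = (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.dx
        y = (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.dy
        return np.meshgrid(x, y)

    def max_radius(self) -> float:
        """Distance from the origin to the farthest pixel center (corner)."""
        X, Y = self.coords()
        return float(np.hypot(X, Y).max())


@dataclass(frozen=True)
class DASConfig:
    radius_assumed: float
    c_assumed: float = 1500.0
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        if self.radius_assumed <= 0:
            raise ConfigurationError("assumed radius must be positive")
        if self.c_assumed <= 0:
            raise ConfigurationError("assumed speed of sound must be positive")
        if self.interpolation not in ("nearest", "linear"):
            raise ConfigurationError("interpolation must be 'nearest' or 'linear'")


def time_of_flight(sensor_angle: float, pixel: tuple[float, float], config: DASConfig) -> float:
    """Travel time from the assumed sensor position to a pixel (seconds)."""
    sx = config.radius_assumed * np.cos(sensor_angle)
    sy = config.radius_assumed * np.sin(sensor_angle)
    return float(np.hypot(pixel[0] - sx, pixel[1] - sy) / config.c_assumed)


def das_reconstruct(sino: Sinogram, ring_angles: np.ndarray, config: DASConfig,
                    grid: ReconGrid) -> np.ndarray:
    """Plain delay-and-sum: image(Q) = sum_i p_i(t_i(Q)).

    Linear in the sinogram; delays falling outside the recorded window
    contribute zero.  No apodization or weighting is applied.
    """
    angles = np.asarray(ring_angles, dtype=np.float64)
    if angles.ndim != 1 or angles.size != sino.n_sensors:
        raise ShapeError(
            f"ring_angles length {angles.size} != sinogram channels {sino.n_sensors}"
        )
    if grid.max_radius() >= config.radius_assumed:
        raise GeometryError("reconstruction grid extends outside the assumed sensor ring")

    X, Y = grid.coords()
    image = np.zeros((grid.ny, grid.nx), dtype=np.float64)
    data = sino.data
    n_t = sino.n_t
    for i, ang in enumerate(angles):
        sx = config.radius_assumed * np.cos(ang)
        sy = config.radius_assumed * np.sin(ang)
        t = np.hypot(X - sx, Y - sy) / config.c_assumed
        s = (t - sino.t0) * sino.fs  # fractional sample index
        if config.interpolation == "nearest":
            idx = np.rint(s).astype(np.int64)
            valid = (idx >= 0) & (idx <= n_t - 1)
            contrib = np.where(valid, data[i, np.clip(idx, 0, n_t - 1)], 0.0)
        else:
            i0 = np.floor(s).astype(np.int64)
            frac = s - i0
            v0 = (i0 >= 0) & (i0 <= n_t - 1)
            v1 = (i0 + 1 >= 0) & (i0 + 1 <= n_t - 1)
            c0 = np.where(v0, data[i, np.clip(i0, 0, n_t - 1)], 0.0)
            c1 = np.where(v1, data[i, np.clip(i0 + 1, 0, n_t - 1)], 0.0)
            contrib = (1.0 - frac) * c0 + frac * c1
        image += contrib
    return image


def max_normalize(image: np.ndarray) -> np.ndarray:
    """Divide by the maximum absolute pixel value (no-op for all-zero input)."""
    peak = float(np.abs(image).max())
    return image / peak if peak > 0 else image.copy()


def radius_grid(r_min: float, r_max: float, step: float) -> np.ndarray:
    """Inclusive ascending radius sweep with exact integer-indexed spacing."""
    if step <= 0:
        raise ConfigurationError("step must be positive")
    if r_min > r_max:
        raise ConfigurationError("r_min must be <= r_max")
    n = int(np.floor((r_max - r_min) / step + 1e-9))
    return r_min + step * np.arange(n + 1)


def save_image(path, image: np.ndarray, *, radius_assumed: float,
               c_assumed: float) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("img", data=image)
        ds.attrs["radius_assumed"] = radius_assumed
        ds.attrs["c_assumed"] = c_assumed


def export_png(path, image: np.ndarray) -> None:
    """8-bit PNG export of a max-normalized image (absolute value)."""
    from PIL import Image as PILImage

    norm = np.abs(max_normalize(image))
    PILImage.fromarray((norm * 255).astype(np.uint8)).save(path)
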