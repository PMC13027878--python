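"""Synthetic 2D initial-pressure maps (virtual phantoms).

A phantom is the optical-absorption / initial-pressure field ``p0(r)`` that a
laser pulse would deposit in tissue.  Real studies derive these from anatomical
images; here they are generated procedurally in four families that emulate the
structural variety of such sources: point-like/circular/elliptical absorbers,
irregular curvilinear structures, and vascular-like branching trees.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np
import yaml
from PIL import Image
from scipy import ndimage

from srcorrect.errors import ConfigurationError

FAMILIES = ("points_disks_ellipses", "curvilinear", "vascular_tree", "mixed")


@dataclass(frozen=True)
class PressureMap:
    """2D non-negative initial-pressure field with physical pixel size.

    ``values`` is normalized to [0, 1]; ``dx``/``dy`` are pixel sizes in
    meters.
    """

    values: np.ndarray
    dx: float
    dy: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.size == 0:
            raise ConfigurationError("pressure map must be a non-empty 2D array")
        if self.dx <= 0 or self.dy <= 0:
            raise ConfigurationError("pixel sizes must be positive")
        if np.any(v < 0) or (v.size and np.nanmax(v) > 1 + 1e-12):
            raise ConfigurationError("pressure values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one procedural phantom.

    ``n_points/n_disks/n_ellipses/n_curves/n_trees`` are structure counts,
    drawn only for the families that use them; sizes are in pixels.
    ``placement_frac`` confines structure centers to a disk of that fraction
    of the half-canvas, so sources stay inside the detection ring's field of
    view.
    """

    family: str = "mixed"
    canvas: int = 128
    seed: int = 0
    n_points: int = 3
    n_disks: int = 3
    n_ellipses: int = 2
    n_curves: int = 2
    n_trees: int = 1
    disk_radius: tuple[float, float] = (2.0, 8.0)
    ellipse_axis: tuple[float, float] = (3.0, 12.0)
    curve_width: tuple[float, float] = (1.0, 4.0)
    intensity: tuple[float, float] = (0.3, 1.0)
    placement_frac: float = 0.62
    non_overlapping: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown phantom family {self.family!r}")
        if self.canvas <= 0:
            raise ConfigurationError("canvas must be positive")
        for name in ("n_points", "n_disks", "n_ellipses", "n_curves", "n_trees"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("disk_radius", "ellipse_axis", "curve_width"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigurationError(f"{name} range must be positive and ordered")
        if not 0 < self.placement_frac <= 1:
            raise ConfigurationError("placement_frac must be in (0, 1]")
        if max(self.disk_radius[1], self.ellipse_axis[1]) * 2 > self.canvas:
            raise ConfigurationError("structure larger than canvas")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("disk_radius", "ellipse_axis", "curve_width", "intensity"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _grid_coords(n: int) -> tuple[np.ndarray, np.ndarray]:
    c = (n - 1) / 2.0
    y, x = np.mgrid[0:n, 0:n]
    return y - c, x - c


def _draw_disk(canvas: np.ndarray, cy: float, cx: float, r: float, amp: float) -> None:
    n = canvas.shape[0]
    y, x = _grid_coords(n)
    c = (n - 1) / 2.0
    mask = (y - (cy - c)) ** 2 + (x - (cx - c)) ** 2 <= r * r
    canvas[mask] = np.maximum(canvas[mask], amp)


def _draw_ellipse(canvas, cy, cx, a, b, theta, amp) -> None:
    n = canvas.shape[0]
    y, x = np.mgrid[0:n, 0:n]
    yr, xr = y - cy, x - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * xr + st * yr
    v = -st * xr + ct * yr
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    canvas[mask] = np.maximum(canvas[mask], amp)


def _stamp_path(canvas, ys, xs, width, amp) -> None:
    """Rasterize a polyline by dilating the visited pixels to ``width``."""
    n = canvas.shape[0]
    trace = np.zeros((n, n), dtype=bool)
    iy = np.clip(np.round(ys).astype(int), 0, n - 1)
    ix = np.clip(np.round(xs).astype(int), 0, n - 1)
    trace[iy, ix] = True
    radius = max(int(round(width / 2.0)), 0)
    if radius > 0:
        trace = ndimage.binary_dilation(trace, ndimage.generate_binary_structure(2, 1), iterations=radius)
    canvas[trace] = np.maximum(canvas[trace], amp)


def _random_center(rng, n: int, frac: float, margin: float = 0.0) -> tuple[float, float]:
    c = (n - 1) / 2.0
    rmax = max(frac * n / 2.0 - margin, 1.0)
    r = rmax * np.sqrt(rng.uniform())
    phi = rng.uniform(0, 2 * np.pi)
    return c + r * np.sin(phi), c + r * np.cos(phi)


def _place_disks(canvas, rng, spec: PhantomSpec, count: int, radius_range) -> None:
    placed: list[tuple[float, float, float]] = []
    for _ in range(count):
        r = rng.uniform(*radius_range)
        for _attempt in range(200):
            cy, cx = _random_center(rng, spec.canvas, spec.placement_frac, margin=r)
            if not spec.non_overlapping:
                break
            # keep >= 2 px clearance so binarized components stay distinct
            if all(np.hypot(cy - py, cx - px) >= r + pr + 2.0 for py, px, pr in placed):
                break
        placed.append((cy, cx, r))
        _draw_disk(canvas, cy, cx, r, rng.uniform(*spec.intensity))


def _add_curves(canvas, rng, spec: PhantomSpec, count: int) -> None:
    n = spec.canvas
    for _ in range(count):
        cy, cx = _random_center(rng, n, spec.placement_frac)
        length = int(rng.integers(n // 6, n // 2))
        theta = rng.uniform(0, 2 * np.pi)
        ys, xs = [cy], [cx]
        for _step in range(length):
            theta += rng.normal(0.0, 0.3)  # correlated random walk
            ys.append(ys[-1] + np.sin(theta))
            xs.append(xs[-1] + np.cos(theta))
        ys_arr = ndimage.uniform_filter1d(np.asarray(ys), size=5)
        xs_arr = ndimage.uniform_filter1d(np.asarray(xs), size=5)
        _stamp_path(canvas, ys_arr, xs_arr, rng.uniform(*spec.curve_width), rng.uniform(*spec.intensity))


def _add_tree(canvas, rng, spec: PhantomSpec) -> None:
    n = spec.canvas
    root = _random_center(rng, n, spec.placement_frac * 0.6)
    stack = [(root[0], root[1], rng.uniform(0, 2 * np.pi), n / 5.0, spec.curve_width[1], 0)]
    amp = rng.uniform(*spec.intensity)
    while stack:
        cy, cx, theta, length, width, depth = stack.pop()
        steps = max(int(length), 2)
        ys = cy + np.sin(theta) * np.arange(steps)
        xs = cx + np.cos(theta) * np.arange(steps)
        _stamp_path(canvas, ys, xs, width, amp)
        if depth < 3 and width > spec.curve_width[0]:
            for sign in (-1.0, 1.0):
                stack.append(
                    (ys[-1], xs[-1], theta + sign * rng.uniform(0.3, 0.8),
                     length * 0.7, width * 0.6, depth + 1)
                )


def generate_phantom(spec: PhantomSpec, dx: float = 2.0e-4, dy: float | None = None) -> PressureMap:
    """Generate one procedural phantom; bit-identical for a fixed seed."""
    dy = dx if dy is None else dy
    rng = np.random.default_rng(spec.seed)
    canvas = np.zeros((spec.canvas, spec.canvas), dtype=np.float64)
    fam = spec.family
    if fam in ("points_disks_ellipses", "mixed"):
        _place_disks(canvas, rng, spec, spec.n_points, (1.0, 2.0))
        _place_disks(canvas, rng, spec, spec.n_disks, spec.disk_radius)
        for _ in range(spec.n_ellipses):
            a = rng.uniform(*spec.ellipse_axis)
            b = rng.uniform(spec.ellipse_axis[0], a)
            cy, cx = _random_center(rng, spec.canvas, spec.placement_frac, margin=a)
            _draw_ellipse(canvas, cy, cx, a, b, rng.uniform(0, np.pi), rng.uniform(*spec.intensity))
    if fam in ("curvilinear", "mixed"):
        _add_curves(canvas, rng, spec, spec.n_curves)
    if fam in ("vascular_tree", "mixed"):
        for _ in range(spec.n_trees):
            _add_tree(canvas, rng, spec)
    return PressureMap(values=np.clip(canvas, 0.0, 1.0), dx=dx, dy=dy)


def load_image_phantom(path, dx: float = 4.0e-5, dy: float | None = None) -> PressureMap:
    """Load a grayscale image as an initial-pressure map, min-max normalized.

    Constant images (max == min) map to all zeros rather than dividing by
    zero.
    """
    dy = dx if dy is None else dy
    try:
        with Image.open(path) as img:
            arr = np.asarray(img.convert("F"), dtype=np.float64)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image phantom from {path!r}: {exc}") from exc
    if arr.size == 0:
        raise OSError(f"empty image at {path!r}")
    lo, hi = float(arr.min()), float(arr.max())
    values = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    return PressureMap(values=values, dx=dx, dy=dy)


def pad_to_grid(pmap: PressureMap, target_n: int) -> PressureMap:
    """Zero-pad a map to ``target_n`` × ``target_n`` with the content centered."""
    ny, nx = pmap.values.shape
    if target_n < max(nx, ny):
        raise ConfigurationError(
            f"target grid {target_n} smaller than input {ny}x{nx}"
        )
    top = (target_n - ny) // 2
    left = (target_n - nx) // 2
    out = np.zeros((target_n, target_n), dtype=pmap.values.dtype)
    out[top:top + ny, left:left + nx] = pmap.values
    return PressureMap(values=out, dx=pmap.dx, dy=pmap.dy)


def save_pressure_map(path, pmap: PressureMap) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("phantom", data=pmap.values)
        ds.attrs["dx"] = pmap.dx
        ds.attrs["dy"] = pmap.dy


def load_pressure_map(path) -> PressureMap:
    with h5py.File(path, "r") as fh:
        ds = fh["phantom"]
        return PressureMap(values=ds[()], dx=float(ds.attrs["dx"]), dy=float(ds.attrs["dy"]))
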