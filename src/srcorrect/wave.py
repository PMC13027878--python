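"""Forward acoustic simulation for ring-array photoacoustic tomography.

Solves the lossless linear wave equation as an initial-value problem
(p(0) = p0, dp/dt(0) = 0) with a first-order coupled k-space pseudospectral
scheme: spectral spatial derivatives on staggered grids with the exact
k-space dispersion correction sinc(c·k·dt/2), leapfrog time stepping, and a
split-field perfectly matched layer (PML) absorbing the outgoing wave at the
domain edge.  For a homogeneous medium this scheme is dispersion-free for
all supported wavenumbers, so arrival times are accurate to the grid scale.

Time-resolved pressure is sampled at the ring sensor positions by bilinear
interpolation, then band-limited by the transducer response and optionally
contaminated with calibrated white noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import h5py
import numpy as np
from scipy import fft as sfft

from srcorrect.errors import ConfigurationError, GeometryError
from srcorrect.phantoms import PressureMap


@dataclass(frozen=True)
class Medium:
    """Homogeneous acoustic medium.

    ``alpha0`` (dB/(MHz·cm)) is carried for provenance only; absorption is
    not modeled in the time stepping.
    """

    c: float = 1500.0
    rho: float = 1000.0
    alpha0: float = 0.5

    def __post_init__(self) -> None:
        if self.c <= 0 or self.rho <= 0:
            raise ConfigurationError("speed of sound and density must be positive")
        if self.alpha0 < 0:
            raise ConfigurationError("absorption coefficient must be >= 0")


@dataclass(frozen=True)
class SensorRing:
    """Circular detection array: geometry plus transducer response.

    ``radius`` is the true scanning radius (meters); sensors sit at
    ``n_sensors`` evenly spaced angles starting at 0.  ``f0`` and ``frac_bw``
    describe the Gaussian −6 dB band of each element.
    """

    n_sensors: int
    radius: float
    center: tuple[float, float] = (0.0, 0.0)
    f0: float = 5.0e6
    frac_bw: float = 0.7

    def __post_init__(self) -> None:
        if self.n_sensors < 3:
            raise GeometryError("ring needs at least 3 sensors")
        if self.radius <= 0:
            raise GeometryError("ring radius must be positive")
        if not 0 < self.frac_bw < 2:
            raise ConfigurationError("fractional bandwidth must be in (0, 2)")

    @property
    def angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_sensors) / self.n_sensors

    def positions(self) -> np.ndarray:
        """(n_sensors, 2) Cartesian sensor coordinates (x, y) in meters."""
        a = self.angles
        cx, cy = self.center
        return np.stack([cx + self.radius * np.cos(a), cy + self.radius * np.sin(a)], axis=1)


@dataclass(frozen=True)
class Sinogram:
    """n_sensors × n_t RF record with sampling rate ``fs`` and start time ``t0``."""

    data: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=np.float64)
        if d.ndim != 2 or d.shape[1] < 1:
            raise ConfigurationError("sinogram must be a 2D (n_sensors, n_t) array")
        if not np.all(np.isfinite(d)):
            raise ConfigurationError("sinogram contains non-finite entries")
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        object.__setattr__(self, "data", d)

    @property
    def n_sensors(self) -> int:
        return self.data.shape[0]

    @property
    def n_t(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_t) / self.fs


def _smooth_source(p0: np.ndarray) -> np.ndarray:
    """Spectral Blackman smoothing of the source to limit grid-scale ringing."""
    ny, nx = p0.shape
    wy = np.blackman(ny)
    wx = np.blackman(nx)
    # frequency-domain window centered on DC
    fy = np.fft.ifftshift(wy)[:, None]
    fx = np.fft.ifftshift(wx)[None, :]
    spec = np.fft.fft2(p0) * fy * fx
    # no peak restoration: the solver must stay exactly linear in p0
    return np.real(np.fft.ifft2(spec))


def _pml_profile(n: int, pml_size: int, alpha_max: float, c: float, dx: float,
                 staggered: bool) -> np.ndarray:
    """Exponential PML attenuation per half time step along one axis."""
    x = np.arange(n, dtype=np.float64)
    if staggered:
        x = x + 0.5
    left = np.clip(pml_size - x, 0.0, None) / pml_size
    right = np.clip(x - (n - 1 - pml_size), 0.0, None) / pml_size
    prof = alpha_max * (c / dx) * (np.maximum(left, right) ** 4)
    return prof


def simulate_rf(
    p0: PressureMap,
    medium: Medium,
    ring: SensorRing,
    n_t: int,
    fs: float,
    *,
    cfl: float = 0.3,
    pml_size: int = 20,
    pml_alpha: float = 2.0,
    smooth_source: bool = True,
) -> Sinogram:
    """Propagate ``p0`` through the medium and record pressure at the ring.

    The computational grid is expanded (and zero-padded) as needed so the
    ring sits inside the interior region with a margin in front of the PML;
    the internal time step satisfies the CFL bound and divides the requested
    sampling interval exactly, so output samples need no resampling.
    The output is linear in ``p0``.
    """
    if n_t < 1:
        raise ConfigurationError("n_t must be >= 1")
    if fs <= 0:
        raise ConfigurationError("fs must be positive")
    if abs(p0.dx - p0.dy) > 1e-12:
        raise ConfigurationError("solver requires square pixels (dx == dy)")
    dx = p0.dx
    c, rho0 = medium.c, medium.rho

    # --- grid: centered source, ring + 8-cell margin + PML inside the domain
    half_needed = ring.radius / dx + pml_size + 8
    n_grid = int(2 * math.ceil(half_needed) + 1)
    n_grid = max(n_grid, max(p0.values.shape) )
    n_grid = sfft.next_fast_len(n_grid)
    field = np.zeros((n_grid, n_grid), dtype=np.float64)
    ny, nx = p0.values.shape
    top, left = (n_grid - ny) // 2, (n_grid - nx) // 2
    field[top:top + ny, left:left + nx] = p0.values

    # physical coordinates: grid center = ring center assumed at origin
    center_idx = (n_grid - 1) / 2.0
    interior_half = (n_grid / 2.0 - pml_size - 2) * dx
    if ring.radius >= interior_half:
        raise GeometryError("sensor ring does not fit inside the computational domain")
    # sources must not touch the PML
    src_rows, src_cols = np.nonzero(field)
    if src_rows.size:
        max_off = max(
            np.abs(src_rows - center_idx).max(), np.abs(src_cols - center_idx).max()
        ) * dx
        if max_off >= interior_half:
            raise GeometryError("source extends into the absorbing boundary layer")

    # --- time step: dt = 1/(fs*m) <= cfl*dx/c
    dt_cfl = cfl * dx / c
    m = max(1, math.ceil(1.0 / (fs * dt_cfl)))
    dt = 1.0 / (fs * m)
    if dt > dt_cfl * (1 + 1e-9):
        raise ConfigurationError("unstable time step")
    n_steps = (n_t - 1) * m

    # --- spectral operators on the half-spectrum (rfft2 layout), staggered
    # derivatives with the k-space dispersion correction
    k_full = 2.0 * np.pi * np.fft.fftfreq(n_grid, d=dx)
    k_half = 2.0 * np.pi * np.fft.rfftfreq(n_grid, d=dx)
    kx = k_half[None, :]
    ky = k_full[:, None]
    kmag = np.sqrt(kx ** 2 + ky ** 2)
    kappa = np.sinc(c * dt * kmag / (2.0 * np.pi))  # np.sinc(x) = sin(pi x)/(pi x)
    ddx_pos = (1j * kx * kappa * np.exp(1j * kx * dx / 2.0)).astype(np.complex64)
    ddx_neg = (1j * kx * kappa * np.exp(-1j * kx * dx / 2.0)).astype(np.complex64)
    ddy_pos = (1j * ky * kappa * np.exp(1j * ky * dx / 2.0)).astype(np.complex64)
    ddy_neg = (1j * ky * kappa * np.exp(-1j * ky * dx / 2.0)).astype(np.complex64)

    ax = _pml_profile(n_grid, pml_size, pml_alpha, c, dx, staggered=False)[None, :]
    ax_sg = _pml_profile(n_grid, pml_size, pml_alpha, c, dx, staggered=True)[None, :]
    ay = _pml_profile(n_grid, pml_size, pml_alpha, c, dx, staggered=False)[:, None]
    ay_sg = _pml_profile(n_grid, pml_size, pml_alpha, c, dx, staggered=True)[:, None]
    pml_x = np.exp(-ax * dt / 2.0).astype(np.float32)
    pml_x_sg = np.exp(-ax_sg * dt / 2.0).astype(np.float32)
    pml_y = np.exp(-ay * dt / 2.0).astype(np.float32)
    pml_y_sg = np.exp(-ay_sg * dt / 2.0).astype(np.float32)

    # --- sensor interpolation stencil (bilinear)
    pos = ring.positions()
    gx = pos[:, 0] / dx + center_idx
    gy = pos[:, 1] / dx + center_idx
    ix0 = np.floor(gx).astype(int)
    iy0 = np.floor(gy).astype(int)
    fx_w = gx - ix0
    fy_w = gy - iy0
    w00 = (1 - fy_w) * (1 - fx_w)
    w01 = (1 - fy_w) * fx_w
    w10 = fy_w * (1 - fx_w)
    w11 = fy_w * fx_w

    def sample(p: np.ndarray) -> np.ndarray:
        return (
            w00 * p[iy0, ix0] + w01 * p[iy0, ix0 + 1]
            + w10 * p[iy0 + 1, ix0] + w11 * p[iy0 + 1, ix0 + 1]
        )

    # --- initial conditions (single-precision fields, half-spectrum FFTs)
    p = (_smooth_source(field) if smooth_source else field).astype(np.float32)
    rho_x = p / np.float32(2.0 * c * c)
    rho_y = rho_x.copy()
    p_hat = sfft.rfft2(p)
    # half-step velocity start realizes dp/dt(0) = 0 to second order
    ux = np.float32(-(dt / 2.0) / rho0) * sfft.irfft2(ddx_pos * p_hat, s=p.shape)
    uy = np.float32(-(dt / 2.0) / rho0) * sfft.irfft2(ddy_pos * p_hat, s=p.shape)

    dt_rho = np.float32(dt / rho0)
    dt_rho0 = np.float32(dt * rho0)
    c2 = np.float32(c * c)
    out = np.empty((ring.n_sensors, n_t), dtype=np.float64)
    out[:, 0] = sample(p)
    rec = 1
    for step in range(1, n_steps + 1):
        if step > 1:
            p_hat = sfft.rfft2(p)
            ux = pml_x_sg * (pml_x_sg * ux - dt_rho * sfft.irfft2(ddx_pos * p_hat, s=p.shape))
            uy = pml_y_sg * (pml_y_sg * uy - dt_rho * sfft.irfft2(ddy_pos * p_hat, s=p.shape))
        dux = sfft.irfft2(ddx_neg * sfft.rfft2(ux), s=p.shape)
        duy = sfft.irfft2(ddy_neg * sfft.rfft2(uy), s=p.shape)
        rho_x = pml_x * (pml_x * rho_x - dt_rho0 * dux)
        rho_y = pml_y * (pml_y * rho_y - dt_rho0 * duy)
        p = c2 * (rho_x + rho_y)
        if step % m == 0:
            out[:, rec] = sample(p)
            rec += 1
    assert rec == n_t
    return Sinogram(data=out, fs=fs, t0=0.0)


def apply_transducer_band(sino: Sinogram, f0: float, frac_bw: float) -> Sinogram:
    """Zero-phase Gaussian band-pass with a −6 dB fractional bandwidth.

    The amplitude response is exp(-(|f|-f0)^2 / (2 sigma^2)) with sigma set
    so the response is exactly 0.5 at f0*(1 ± frac_bw/2); DC is removed.
    """
    if f0 >= sino.fs / 2.0:
        raise ConfigurationError("transducer center frequency must be below Nyquist")
    if not 0 < frac_bw < 2:
        raise ConfigurationError("fractional bandwidth must be in (0, 2)")
    n = sino.n_t
    freqs = np.fft.rfftfreq(n, d=1.0 / sino.fs)
    sigma = (f0 * frac_bw / 2.0) / math.sqrt(2.0 * math.log(2.0))
    h = np.exp(-((freqs - f0) ** 2) / (2.0 * sigma ** 2))
    h[0] = 0.0
    spec = np.fft.rfft(sino.data, axis=1) * h[None, :]
    return Sinogram(data=np.fft.irfft(spec, n=n, axis=1), fs=sino.fs, t0=sino.t0)


def add_white_noise(sino: Sinogram, level_db: float, rng) -> Sinogram:
    """Add Gaussian white noise at ``level_db`` relative to the peak amplitude.

    sigma = 10^(level_db/20) × max|data| over the whole sinogram (amplitude
    convention, peak reference).  All-zero input is returned unchanged with a
    warning.
    """
    peak = float(np.abs(sino.data).max())
    if peak == 0.0:
        warnings.warn("all-zero sinogram: noise scale undefined, returning input unchanged")
        return Sinogram(data=sino.data.copy(), fs=sino.fs, t0=sino.t0)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sigma = 10.0 ** (level_db / 20.0) * peak
    noisy = sino.data + gen.normal(0.0, sigma, size=sino.data.shape)
    return Sinogram(data=noisy, fs=sino.fs, t0=sino.t0)


def save_sinogram(path, sino: Sinogram, *, radius_true: float | None = None,
                  c: float | None = None, seed: int | None = None) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("rf", data=sino.data)
        ds.attrs["fs"] = sino.fs
        ds.attrs["t0"] = sino.t0
        if radius_true is not None:
            ds.attrs["radius_true"] = radius_true
        if c is not None:
            ds.attrs["c"] = c
        if seed is not None:
            ds.attrs["seed"] = seed


def load_sinogram(path) -> tuple[Sinogram, dict]:
    with h5py.File(path, "r") as fh:
        ds = fh["rf"]
        attrs = dict(ds.attrs)
        return Sinogram(data=ds[()], fs=float(attrs.pop("fs")), t0=float(attrs.pop("t0"))), attrs
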