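"""Shared fixtures: small simulated sinograms and reconstruction helpers.

Simulations are session-scoped so the (CPU-heavy) forward solver runs once
per geometry and is reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from srcorrect.das import DASConfig, ReconGrid, das_reconstruct
from srcorrect.phantoms import PressureMap
from srcorrect.wave import Medium, SensorRing, apply_transducer_band, simulate_rf

DESK_DX = 2.0e-4
DESK_RADIUS = 14.0e-3
DESK_FS = 25.0e6
DESK_NT = 512


def disk_map(n: int, cy: float, cx: float, radius_px: float, dx: float = DESK_DX) -> PressureMap:
    yy, xx = np.mgrid[0:n, 0:n]
    canvas = np.zeros((n, n))
    canvas[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px ** 2] = 1.0
    return PressureMap(values=canvas, dx=dx, dy=dx)


@pytest.fixture(scope="session")
def medium() -> Medium:
    return Medium()


@pytest.fixture(scope="session")
def desk_ring() -> SensorRing:
    return SensorRing(n_sensors=32, radius=DESK_RADIUS, f0=2.0e6, frac_bw=0.7)


@pytest.fixture(scope="session")
def offcenter_disk():
    """Disk of radius 0.5 mm centered at (x, y) = (+4, −2) mm on the 128-grid."""
    n = 128
    c0 = (n - 1) / 2
    pmap = disk_map(n, c0 - 10, c0 + 20, 2.5)
    return pmap, (4.0e-3, -2.0e-3), 0.5e-3


@pytest.fixture(scope="session")
def offcenter_sino(offcenter_disk, medium, desk_ring):
    pmap, _, _ = offcenter_disk
    return simulate_rf(pmap, medium, desk_ring, DESK_NT, DESK_FS)


@pytest.fixture(scope="session")
def centered_sino(medium, desk_ring):
    n = 128
    c0 = (n - 1) / 2
    return simulate_rf(disk_map(n, c0, c0, 5.0), medium, desk_ring, DESK_NT, DESK_FS)


@pytest.fixture(scope="session")
def ring_artifact_peaks(medium):
    """Radial position (in 0.1 mm recon pixels) of the ring artifact that a
    centered point source develops under four scanning-radius errors."""
    dx = 8.0e-5
    n = 64
    ring = SensorRing(n_sensors=128, radius=12.0e-3, f0=6.5e6, frac_bw=0.7)
    canvas = np.zeros((n, n))
    canvas[n // 2, n // 2] = 1.0
    p0 = PressureMap(values=canvas, dx=dx, dy=dx)
    sino = apply_transducer_band(simulate_rf(p0, medium, ring, 640, 62.5e6),
                                 ring.f0, ring.frac_bw)
    grid = ReconGrid(nx=64, ny=64, dx=1.0e-4, dy=1.0e-4)
    Y, X = grid.coords()
    # the single-pixel source sits half a pixel off the exact grid center
    r = np.hypot(X - dx / 2, Y - dx / 2)
    peaks = {}
    for d_r in (-8.0e-4, -4.0e-4, 4.0e-4, 8.0e-4):
        img = np.abs(das_reconstruct(
            sino, ring.angles, DASConfig(radius_assumed=ring.radius + d_r), grid))
        profile = np.array([
            img[(r >= b * 1.0e-4) & (r < (b + 1) * 1.0e-4)].mean() for b in range(25)
        ])
        peaks[d_r] = int(np.argmax(profile))
    return peaks
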