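"""Image-quality metrics, dB-compressed display, error maps and aggregation.

The similarity index here is the *global* form — single means, standard
deviations and covariance over the whole image with stabilizing constants
C1 = 0.01 and C2 = 0.03 — rather than the windowed variant with (K·L)²
constants; a windowed alternative (scikit-image) is available behind a flag
for comparison.  All metrics are intended for images normalized by their
highest pixel value.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from srcorrect.das import max_normalize
from srcorrect.dataset import TrainingPair, normalize_pair, replicate_channels
from srcorrect.errors import ConfigurationError, ShapeError

C1_DEFAULT = 0.01
C2_DEFAULT = 0.03


def _check(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ShapeError(f"image shapes differ: {x.shape} vs {y.shape}")


def mse(x: np.ndarray, y: np.ndarray) -> float:
    _check(x, y)
    return float(np.mean((np.asarray(x, float) - np.asarray(y, float)) ** 2))


def psnr(x: np.ndarray, y: np.ndarray, L: float = 1.0) -> float:
    """10·log10(L²/MSE); identical images give +inf."""
    err = mse(x, y)
    if err == 0.0:
        return math.inf
    return float(10.0 * np.log10(L * L / err))


def ssim_global(x: np.ndarray, y: np.ndarray, C1: float = C1_DEFAULT,
                C2: float = C2_DEFAULT, windowed: bool = False) -> float:
    """Whole-image structural similarity with additive constants C1, C2.

    With ``windowed=True`` the scikit-image sliding-window SSIM is returned
    instead (comparison only; different constant convention).
    """
    _check(x, y)
    if x.size < 2:
        raise ShapeError("similarity needs at least 2 pixels")
    if windowed:
        from skimage.metrics import structural_similarity

        return float(structural_similarity(np.asarray(x, float), np.asarray(y, float),
                                           data_range=1.0))
    xf = np.asarray(x, float)
    yf = np.asarray(y, float)
    mx, my = xf.mean(), yf.mean()
    vx, vy = xf.var(), yf.var()
    cov = float(np.mean((xf - mx) * (yf - my)))
    return float(((2 * mx * my + C1) * (2 * cov + C2))
                 / ((mx * mx + my * my + C1) * (vx + vy + C2)))


def pcc(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Pearson correlation over pixels; constant input returns (0, flagged)."""
    _check(x, y)
    xf = np.asarray(x, float).ravel()
    yf = np.asarray(y, float).ravel()
    sx, sy = xf.std(), yf.std()
    if sx == 0.0 or sy == 0.0:
        warnings.warn("PCC undefined for constant images; returning 0")
        return 0.0, True
    r = float(np.mean((xf - xf.mean()) * (yf - yf.mean())) / (sx * sy))
    return float(np.clip(r, -1.0, 1.0)), False


def db_compress(image: np.ndarray, floor_db: float = 50.0, eps: float = 1e-12) -> np.ndarray:
    """20·log10(I/max(I) + eps), clipped to [−floor_db, 0] for display."""
    img = np.abs(np.asarray(image, float))
    peak = img.max()
    if peak <= 0:
        raise ConfigurationError("dB compression requires a positive maximum")
    out = 20.0 * np.log10(img / peak + eps)
    return np.clip(out, -floor_db, 0.0)


def abs_error_map(img: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """Pixelwise |img − gt| on images sharing one normalization."""
    _check(img, gt)
    return np.abs(np.asarray(img, float) - np.asarray(gt, float))


@dataclass
class MetricReport:
    """Per-image and aggregated metrics for raw DAS inputs vs corrected outputs."""

    rows: list[dict] = field(default_factory=list)

    def add(self, phantom_id: str, radius: float, method: str, x: np.ndarray,
            gt: np.ndarray) -> None:
        corr, _ = pcc(x, gt)
        self.rows.append({
            "phantom_id": phantom_id, "radius_used": radius, "method": method,
            "psnr": psnr(x, gt), "ssim": ssim_global(x, gt),
            "mse": mse(x, gt), "pcc": corr,
        })

    def aggregate(self, by: str = "method") -> dict:
        groups: dict = {}
        for row in self.rows:
            key = row[by] if by == "method" else (row["method"], row[by])
            groups.setdefault(key, []).append(row)
        out = {}
        for key, rows in groups.items():
            summary = {}
            for m in ("psnr", "ssim", "mse", "pcc"):
                finite = [r[m] for r in rows if math.isfinite(r[m])]
                if finite:
                    summary[m] = float(np.mean(finite))
                else:
                    # all-infinite PSNR means every image matched exactly
                    summary[m] = math.inf if all(r[m] == math.inf for r in rows) else math.nan
            out[key] = summary
        return out

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["phantom_id", "radius_used", "method",
                                "psnr", "ssim", "mse", "pcc"])
            writer.writeheader()
            writer.writerows(self.rows)

    def summary_json(self, path) -> None:
        agg = self.aggregate()
        with open(path, "w") as fh:
            json.dump({str(k): v for k, v in agg.items()}, fh, indent=2)

    def summary_table(self) -> str:
        agg = self.aggregate()
        lines = [f"{'method':<12}{'PSNR':>10}{'SSIM':>10}{'MSE':>12}{'PCC':>10}"]
        for method in sorted(agg):
            s = agg[method]
            lines.append(f"{method:<12}{s['psnr']:>10.2f}{s['ssim']:>10.3f}"
                         f"{s['mse']:>12.5f}{s['pcc']:>10.3f}")
        return "\n".join(lines)


def evaluate_testset(model_fn, test_pairs: list[TrainingPair]) -> MetricReport:
    """Per-image metrics for raw DAS inputs and corrected outputs against GT.

    ``model_fn`` maps a normalized 2D degraded image in [0, 1] to a corrected
    2D image.  Every pair is first brought onto its shared GT-percentile
    scale; the DAS reconstructions (degraded and GT) are then normalized by
    their highest pixel value, while the corrected output — which already
    lives on the shared normalized-intensity scale the network was trained
    on — is compared there directly, clipped to [0, 1].  One consistent
    scaling per pair keeps absolute-error comparisons meaningful.
    """
    if not test_pairs:
        raise ConfigurationError("empty test set")
    report = MetricReport()
    for pair in test_pairs:
        norm, interval = normalize_pair(pair)
        corrected = np.clip(np.asarray(model_fn(norm.degraded), dtype=float), 0.0, 1.0)
        gt_n = max_normalize(norm.gt)
        report.add(pair.phantom_id, pair.radius_used, "das",
                   max_normalize(norm.degraded), gt_n)
        report.add(pair.phantom_id, pair.radius_used, "corrected", corrected, gt_n)
    return report


def model_corrector(model):
    """Wrap an SD-ResNet into the 2D-in/2D-out callable used for evaluation."""

    def _fn(img2d: np.ndarray) -> np.ndarray:
        x = replicate_channels(np.asarray(img2d, dtype=np.float32))[None]
        return model.forward(x, train=False)[0, 0].astype(float)

    return _fn
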