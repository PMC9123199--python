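"""Volumetric similarity metrics: CAD, L2 (with MSE/PSNR), MSSIM, Dice.

All metrics compare a prediction against its reference target on the [0, 1]
display scale.  Definitions:

* CAD (cosine angle distance): ``A.B / (||A|| ||B||)`` over the flattened
  volumes; range [-1, 1], 1 for positively collinear images.
* L2: Euclidean distance ``sqrt(sum (a_i - b_i)^2)``.  MSE = L2^2 / N and
  PSNR = 10 log10(peak^2 / MSE) are linear combinations of the same
  quantity (peak is 1 on display-rescaled data), so reports usually quote
  the L2 norm only.
* MSSIM: mean over all fully-interior sliding windows (stride 1) of the
  three-factor SSIM (luminance x contrast x structure), with local moments
  weighted by a unit-sum circular-symmetric Gaussian of SD 1.5 samples and
  stabilizers C1 = 1e-4, C2 = 9e-4, C3 = 4.5e-4.
* Dice: ``2 |p & q| / (|p| + |q|)`` after binarizing both images at an
  intensity threshold of 0.05 (strictly greater than).

The cohort report aggregates per-volume metrics as mean / SD / max / min
(sample SD, ddof=1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .volume import Volume

__all__ = [
    "MSSIMConfig",
    "MetricReport",
    "cad",
    "l2",
    "mse",
    "psnr",
    "mssim",
    "dice",
    "report",
]


def _flat(a):
    arr = a.data if isinstance(a, Volume) else np.asarray(a)
    return np.ravel(arr).astype(np.float64)


def _grid(a):
    arr = a.data if isinstance(a, Volume) else np.asarray(a)
    return np.asarray(arr, dtype=np.float64)


def cad(a, b) -> float:
    """Cosine angle distance between two equally sized images."""
    x, y = _flat(a), _flat(b)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("CAD is undefined for a zero-norm image")
    return float(np.dot(x, y) / (nx * ny))


def l2(a, b) -> float:
    """Euclidean distance between two equally sized images."""
    x, y = _flat(a), _flat(b)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return float(np.linalg.norm(x - y))


def mse(a, b) -> float:
    x, y = _flat(a), _flat(b)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return float(np.mean((x - y) ** 2))


def psnr(a, b, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio; infinite for identical images."""
    m = mse(a, b)
    if m == 0:
        return math.inf
    return float(10.0 * math.log10(peak * peak / m))


def gaussian_window(shape, sd: float = 1.5) -> np.ndarray:
    """Circular-symmetric Gaussian weights on a window, normalized to unit sum."""
    grids = np.meshgrid(
        *[np.arange(n, dtype=np.float64) - (n - 1) / 2.0 for n in shape],
        indexing="ij",
    )
    r2 = sum(g * g for g in grids)
    w = np.exp(-r2 / (2.0 * sd * sd))
    return w / w.sum()


@dataclass
class MSSIMConfig:
    """Parameters of the windowed structural-similarity computation."""

    window_shape: tuple = (7, 7, 7)
    gaussian_sd: float = 1.5
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    C1: float = 1e-4
    C2: float = 9e-4
    C3: float = 4.5e-4

    def __post_init__(self):
        if any(n < 1 for n in self.window_shape):
            raise ValueError("window_shape entries must be >= 1")
        if min(self.C1, self.C2, self.C3) <= 0:
            raise ValueError("stabilizing constants must be positive")
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("exponents must be non-negative")

    def weights(self) -> np.ndarray:
        return gaussian_window(self.window_shape, self.gaussian_sd)


def window_count(volume_shape, cfg: MSSIMConfig | None = None) -> int:
    """Number of stride-1 windows fully inside a volume."""
    cfg = cfg or MSSIMConfig()
    dims = [n - k + 1 for n, k in zip(volume_shape, cfg.window_shape)]
    if any(d <= 0 for d in dims):
        raise ValueError(
            f"window {cfg.window_shape} does not fit in volume {volume_shape}"
        )
    return int(np.prod(dims))


def mssim(a, b, cfg: MSSIMConfig | None = None):
    """Mean SSIM over all interior windows.

    Returns
    -------
    (float, int)
        The mean SSIM and the number of windows M it averages.
    """
    cfg = cfg or MSSIMConfig()
    x, y = _grid(a), _grid(b)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if any(n < k for n, k in zip(x.shape, cfg.window_shape)):
        raise ValueError(
            f"window {cfg.window_shape} larger than volume {x.shape}"
        )
    w = cfg.weights()
    # The kernel is symmetric, so convolution equals correlation.
    mu_a = fftconvolve(x, w, mode="valid")
    mu_b = fftconvolve(y, w, mode="valid")
    e_aa = fftconvolve(x * x, w, mode="valid")
    e_bb = fftconvolve(y * y, w, mode="valid")
    e_ab = fftconvolve(x * y, w, mode="valid")
    var_a = np.clip(e_aa - mu_a * mu_a, 0.0, None)
    var_b = np.clip(e_bb - mu_b * mu_b, 0.0, None)
    cov = e_ab - mu_a * mu_b
    sd_a = np.sqrt(var_a)
    sd_b = np.sqrt(var_b)
    lum = (2 * mu_a * mu_b + cfg.C1) / (mu_a ** 2 + mu_b ** 2 + cfg.C1)
    con = (2 * sd_a * sd_b + cfg.C2) / (var_a + var_b + cfg.C2)
    stru = (cov + cfg.C3) / (sd_a * sd_b + cfg.C3)
    if cfg.alpha == cfg.beta == cfg.gamma == 1.0:
        ssim_map = lum * con * stru
    else:
        # Non-unit exponents are only meaningful for non-negative factors.
        ssim_map = (lum ** cfg.alpha) * (con ** cfg.beta) * (stru ** cfg.gamma)
    m = ssim_map.size
    return float(ssim_map.mean()), m


def dice(target, pred, threshold: float = 0.05) -> float:
    """Dice overlap of the two images binarized at ``intensity > threshold``.

    Binary inputs pass through unchanged (the threshold sits below 1).
    Raises if both masks are empty, where the ratio is undefined.
    """
    p = _grid(target) > threshold
    q = _grid(pred) > threshold
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    sp = int(p.sum())
    sq = int(q.sum())
    if sp + sq == 0:
        raise ValueError("Dice is undefined: both masks are empty")
    inter = int(np.logical_and(p, q).sum())
    return float(2.0 * inter / (sp + sq))


_METRICS = ["CAD", "L2", "MSE", "PSNR", "MSSIM", "DICE"]


@dataclass
class MetricReport:
    """Per-volume metrics plus cohort mean / SD / max / min."""

    per_pair: pd.DataFrame
    summary: pd.DataFrame
    errors: list = field(default_factory=list)

    def to_csv(self, per_pair_path, summary_path=None):
        self.per_pair.to_csv(per_pair_path, index=False)
        if summary_path is not None:
            self.summary.to_csv(summary_path)


def report(pairs, cfg: MSSIMConfig | None = None,
           dice_threshold: float = 0.05, labels=None) -> MetricReport:
    """Evaluate (target, prediction) pairs and aggregate over the cohort.

    ``pairs`` is a sequence of (target, prediction); each element may be a
    :class:`~ganstrip.volume.Volume` or a bare array on the [0, 1] display
    scale.  Per-pair failures (e.g. empty masks) are recorded in
    ``errors`` and excluded from the aggregates rather than silently
    dropped.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("report needs at least one (target, prediction) pair")
    cfg = cfg or MSSIMConfig()
    rows = []
    errors = []
    for i, (tgt, pred) in enumerate(pairs):
        label = labels[i] if labels is not None else i
        row = {"pair": label}
        try:
            row["CAD"] = cad(tgt, pred)
            row["L2"] = l2(tgt, pred)
            row["MSE"] = mse(tgt, pred)
            row["PSNR"] = psnr(tgt, pred)
            row["MSSIM"] = mssim(tgt, pred, cfg)[0]
            row["DICE"] = dice(tgt, pred, dice_threshold)
        except ValueError as exc:
            errors.append((label, str(exc)))
            for k in _METRICS:
                row.setdefault(k, np.nan)
        rows.append(row)
    per_pair = pd.DataFrame(rows, columns=["pair"] + _METRICS)
    summary = pd.DataFrame(
        {
            "mean": per_pair[_METRICS].mean(),
            "sd": per_pair[_METRICS].std(ddof=1),
            "max": per_pair[_METRICS].max(),
            "min": per_pair[_METRICS].min(),
        }
    )
    return MetricReport(per_pair=per_pair, summary=summary, errors=errors)
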