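"""Quantitative image-quality metrics: PSNR and SSIM, plus set-level aggregation.

Both metrics follow their original formulations:

* PSNR = 10 log10(data_range^2 / MSE), in decibels, with a +inf sentinel at
  MSE = 0;
* SSIM is the mean over sliding windows of
  [(2 mu_x mu_y + C1)(2 sigma_xy + C2)] / [(mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2)],
  C1 = (K1 * range)^2, C2 = (K2 * range)^2, with uniform (unweighted) windows
  and sample (N-1) covariances, evaluated on the interior where the window
  fits fully.

On z-normalized slices there is no nominal intensity range, so ``data_range``
defaults to max - min of the *reference* image of each pair; the value used
is recorded per item so PSNR and SSIM stay comparable across slices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["psnr", "ssim", "evaluate_set", "MetricReport"]

log = logging.getLogger(__name__)


def _check_pair(reference: np.ndarray, test: np.ndarray):
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    if reference.ndim != 2:
        raise ValueError("images must be 2-D")
    return reference, test


def psnr(reference: np.ndarray, test: np.ndarray, data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are identical."""
    reference, test = _check_pair(reference, test)
    if data_range is None:
        data_range = float(reference.max() - reference.min())
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(data_range**2 / mse)


def ssim(
    reference: np.ndarray,
    test: np.ndarray,
    window_size: int = 7,
    K1: float = 0.01,
    K2: float = 0.03,
    data_range: float | None = None,
) -> float:
    """Structural similarity index in [-1, 1]; 1.0 iff the images are identical."""
    reference, test = _check_pair(reference, test)
    if window_size < 3 or window_size % 2 == 0:
        raise ValueError("window_size must be odd and >= 3")
    if min(reference.shape) <= window_size:
        raise ValueError("images must be larger than the window")
    if data_range is None:
        data_range = float(reference.max() - reference.min())
    if data_range <= 0:
        raise ValueError("data_range must be positive")

    x, y = reference, test
    c1 = (K1 * data_range) ** 2
    c2 = (K2 * data_range) ** 2
    win = {"size": window_size, "mode": "reflect"}
    ux = ndimage.uniform_filter(x, **win)
    uy = ndimage.uniform_filter(y, **win)
    uxx = ndimage.uniform_filter(x * x, **win)
    uyy = ndimage.uniform_filter(y * y, **win)
    uxy = ndimage.uniform_filter(x * y, **win)
    np_win = window_size**2
    cov_norm = np_win / (np_win - 1)  # sample covariance
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)

    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    pad = (window_size - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


@dataclass
class MetricReport:
    """Per-item PSNR/SSIM rows plus per-acceleration-factor aggregates."""

    per_item: pd.DataFrame  # case_id, R, psnr_db, ssim, data_range
    aggregate: pd.DataFrame  # R, n, psnr_mean, psnr_sd, ssim_mean, ssim_sd, n_inf_excluded

    def to_csv(self, path) -> None:
        self.per_item.to_csv(path, index=False)


def evaluate_set(pairs) -> MetricReport:
    """Compute PSNR/SSIM per (case, R) pair and aggregate per R.

    ``pairs`` is an iterable of ``(reference, reconstruction, case_id, R)``.
    Aggregates are mean and population standard deviation; items with
    infinite PSNR (identical images) are excluded from the PSNR means with
    a logged count.
    """
    rows = []
    seen = set()
    for reference, recon, case_id, R in pairs:
        key = (case_id, R)
        if key in seen:
            raise ValueError(f"duplicate (case_id, R) pair {key}")
        seen.add(key)
        reference = np.asarray(reference, dtype=float)
        dr = float(reference.max() - reference.min())
        rows.append(
            {
                "case_id": case_id,
                "R": float(R),
                "psnr_db": psnr(reference, recon, data_range=dr),
                "ssim": ssim(reference, recon, data_range=dr),
                "data_range": dr,
            }
        )
    if not rows:
        raise ValueError("pairs must be non-empty")
    per_item = pd.DataFrame(rows)

    agg_rows = []
    for R, grp in per_item.groupby("R", sort=True):
        p = grp["psnr_db"].to_numpy()
        finite = np.isfinite(p)
        n_inf = int((~finite).sum())
        if n_inf:
            log.info("R=%s: excluding %d infinite-PSNR items from the mean", R, n_inf)
        pf = p[finite]
        agg_rows.append(
            {
                "R": R,
                "n": len(grp),
                "psnr_mean": float(pf.mean()) if len(pf) else float("inf"),
                "psnr_sd": float(pf.std()) if len(pf) else 0.0,
                "ssim_mean": float(grp["ssim"].mean()),
                "ssim_sd": float(grp["ssim"].std(ddof=0)),
                "n_inf_excluded": n_inf,
            }
        )
    return MetricReport(per_item=per_item, aggregate=pd.DataFrame(agg_rows))
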