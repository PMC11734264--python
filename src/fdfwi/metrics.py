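"""Image-quality metrics (RMSE, PSNR, SSIM) and report/figure generation.

PSNR has no universal peak convention for physical-unit images; the default
here is the truth map's dynamic range over the evaluation region, and the
convention used is always recorded alongside the number. SSIM follows the
standard: mean local SSIM under an 11x11 Gaussian window (sigma = 1.5) with
K1 = 0.01, K2 = 0.03 and the dynamic-range constant taken from the truth map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.metrics import structural_similarity

from .geometry import Grid, RingArray

__all__ = [
    "MetricReport",
    "rmse",
    "psnr",
    "ssim",
    "evaluate",
    "ring_interior_slices",
    "save_triptych",
]


def _check(recon: np.ndarray, truth: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    recon = np.asarray(recon, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if recon.shape != truth.shape:
        raise ValueError(f"shape mismatch: recon {recon.shape} vs truth {truth.shape}")
    if mask is None:
        mask = np.ones(truth.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != truth.shape:
            raise ValueError("mask shape must match images")
    if not mask.any():
        raise ValueError("metric mask is empty")
    return mask


def rmse(recon: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Root-mean-square error over the masked region, in the maps' units."""
    mask = _check(recon, truth, mask)
    d = np.asarray(recon, float) - np.asarray(truth, float)
    return float(np.sqrt(np.mean(d[mask] ** 2)))


def psnr(
    recon: np.ndarray,
    truth: np.ndarray,
    mask: np.ndarray | None = None,
    peak_mode: str | float = "range",
) -> float:
    """Peak signal-to-noise ratio 20 log10(peak / rmse) in dB.

    ``peak_mode``: ``"range"`` (truth max - min over the mask, default),
    ``"max"`` (truth max), or a fixed numeric peak. Identical images report
    +inf.
    """
    mask = _check(recon, truth, mask)
    truth = np.asarray(truth, float)
    if peak_mode == "range":
        peak = float(truth[mask].max() - truth[mask].min())
    elif peak_mode == "max":
        peak = float(truth[mask].max())
    elif isinstance(peak_mode, (int, float)):
        peak = float(peak_mode)
    else:
        raise ValueError(f"unknown peak_mode {peak_mode!r}")
    e = rmse(recon, truth, mask)
    if e == 0:
        return float("inf")
    return float(20.0 * np.log10(peak / e))


def ssim(
    recon: np.ndarray,
    truth: np.ndarray,
    window: int = 11,
    k1: float = 0.01,
    k2: float = 0.03,
    sigma: float = 1.5,
    data_range: float | None = None,
) -> float:
    """Mean structural similarity with a Gaussian-weighted local window."""
    recon = np.asarray(recon, float)
    truth = np.asarray(truth, float)
    if recon.shape != truth.shape:
        raise ValueError("shape mismatch")
    if window > min(truth.shape):
        raise ValueError(f"SSIM window {window} larger than image {truth.shape}")
    if data_range is None:
        data_range = float(truth.max() - truth.min())
        if data_range == 0:
            data_range = max(abs(float(truth.max())), 1.0)
    return float(
        structural_similarity(
            truth,
            recon,
            win_size=window,
            gaussian_weights=True,
            sigma=sigma,
            K1=k1,
            K2=k2,
            data_range=data_range,
            use_sample_covariance=False,
        )
    )


def ring_interior_slices(grid: Grid, array: RingArray, safety: float = 1.0) -> tuple[slice, slice]:
    """(row, column) slices of the largest axis-aligned square inscribed in the
    ring interior — the default metric evaluation region."""
    half = safety * array.radius / np.sqrt(2.0)
    x0, x1 = array.center[0] - half, array.center[0] + half
    y0, y1 = array.center[1] - half, array.center[1] + half
    ix0 = max(int(np.ceil((x0 - grid.origin[0]) / grid.spacing)), 0)
    ix1 = min(int(np.floor((x1 - grid.origin[0]) / grid.spacing)), grid.nx - 1)
    iy0 = max(int(np.ceil((y0 - grid.origin[1]) / grid.spacing)), 0)
    iy1 = min(int(np.floor((y1 - grid.origin[1]) / grid.spacing)), grid.ny - 1)
    return slice(iy0, iy1 + 1), slice(ix0, ix1 + 1)


@dataclass
class MetricReport:
    """RMSE/PSNR/SSIM of one reconstruction, with the conventions used."""

    rmse: float
    psnr: float
    ssim: float
    region: str = "full"
    conventions: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def evaluate(
    recon: np.ndarray,
    truth: np.ndarray,
    grid: Grid | None = None,
    array: RingArray | None = None,
    peak_mode: str | float = "range",
) -> MetricReport:
    """All three metrics over the inscribed-square ring interior (or the full
    image when no geometry is given)."""
    if grid is not None and array is not None:
        sy, sx = ring_interior_slices(grid, array)
        recon_r, truth_r = recon[sy, sx], truth[sy, sx]
        region = f"inscribed-square rows {sy.start}:{sy.stop} cols {sx.start}:{sx.stop}"
    else:
        recon_r, truth_r = recon, truth
        region = "full"
    return MetricReport(
        rmse=rmse(recon_r, truth_r),
        psnr=psnr(recon_r, truth_r, peak_mode=peak_mode),
        ssim=ssim(recon_r, truth_r),
        region=region,
        conventions={
            "psnr_peak": str(peak_mode),
            "ssim_window": 11,
            "ssim_sigma": 1.5,
            "ssim_k1": 0.01,
            "ssim_k2": 0.03,
            "ssim_data_range": "truth range",
        },
    )


def save_triptych(truth: np.ndarray, recon: np.ndarray, path, title: str = "") -> None:
    """Truth / reconstruction / difference panel figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    vmin, vmax = float(np.min(truth)), float(np.max(truth))
    for ax, img, name in zip(
        axes, [truth, recon, recon - truth], ["truth", "reconstruction", "difference"]
    ):
        kw = {} if name == "difference" else {"vmin": vmin, "vmax": vmax}
        im = ax.imshow(img, origin="lower", **kw)
        ax.set_title(name)
        fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
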