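"""Diffraction-limited spot detection on single-channel field images.

Pipeline per channel image: scale-normalized Laplacian-of-Gaussian response,
robust background statistics (median / scaled MAD) of the response, local
maxima above ``mu + k * sigma``, greedy suppression of maxima closer than the
minimum separation (brighter wins; ties broken by smaller row, col), border
rejection, and intensity-weighted 3x3 sub-pixel centroid refinement. Fully
deterministic: output is sorted by descending peak intensity, ties by
row-major position.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .config import DetectionParams

log = logging.getLogger(__name__)

DETECTION_COLUMNS = [
    "image_id",
    "channel",
    "x_um",
    "y_um",
    "row",
    "col",
    "peak_intensity",
    "background_local",
]


def estimate_background(channel_image: np.ndarray) -> tuple[float, float]:
    """Robust background mean and SD: (median, MAD * 1.4826).

    Insensitive to sparse bright spots. A constant image yields sigma = 0,
    which downstream code treats as a degenerate-background flag.
    """
    img = np.asarray(channel_image, dtype=float)
    if img.size == 0:
        raise ValueError("image is empty")
    mu = float(np.median(img))
    sigma = 1.4826 * float(np.median(np.abs(img - mu)))
    if sigma == 0.0:
        log.warning("constant (or >50%% identical) image: background SD estimated as 0")
    return mu, sigma


def _log_response(img: np.ndarray, sigma_px: float) -> np.ndarray:
    # negated, scale-normalized LoG: positive at bright blobs of scale sigma
    return -(sigma_px**2) * ndi.gaussian_laplace(np.asarray(img, dtype=float), sigma_px)


def detect_spots(
    channel_image: np.ndarray,
    params: DetectionParams,
    pixel_size_um: float = 0.1,
    image_id: str = "",
    channel: int = 0,
) -> pd.DataFrame:
    """Detect diffraction-limited spots in one channel image.

    Returns a DataFrame with columns ``image_id, channel, x_um, y_um, row, col,
    peak_intensity, background_local`` sorted by descending peak intensity
    (ties by row, col). ``peak_intensity`` is the raw image value at the peak
    pixel; ``background_local`` the robust raw background mean.
    """
    img = np.asarray(channel_image, dtype=float)
    resp = _log_response(img, params.log_sigma_px)
    mu_r, sd_r = estimate_background(resp)
    if sd_r == 0.0:
        threshold = mu_r + params.abs_floor
        log.warning("zero background SD in LoG response; absolute floor %g used",
                    params.abs_floor)
    else:
        threshold = mu_r + params.k_threshold * sd_r

    # local maxima of the response above threshold
    footprint = np.ones((3, 3), dtype=bool)
    maxima = (resp == ndi.maximum_filter(resp, footprint=footprint)) & (resp > threshold)
    rows, cols = np.nonzero(maxima)
    if rows.size == 0:
        return pd.DataFrame(columns=DETECTION_COLUMNS)

    # greedy non-maximum suppression: brighter first, ties by (row, col)
    vals = resp[rows, cols]
    order = np.lexsort((cols, rows, -vals))
    rows, cols, vals = rows[order], cols[order], vals[order]
    kept: list[int] = []
    min_sep2 = params.min_separation_px**2
    for i in range(rows.size):
        ok = True
        for j in kept:
            if (rows[i] - rows[j]) ** 2 + (cols[i] - cols[j]) ** 2 < min_sep2:
                ok = False
                break
        if ok:
            kept.append(i)
    rows, cols = rows[kept], cols[kept]

    # border policy: centers within 3*sigma of the edge are unreliable
    border = int(math.ceil(3 * params.log_sigma_px))
    n = img.shape
    inside = (
        (rows >= border)
        & (rows < n[0] - border)
        & (cols >= border)
        & (cols < n[1] - border)
    )
    rows, cols = rows[inside], cols[inside]

    mu_raw, _ = estimate_background(img)
    records = []
    for r, c in zip(rows, cols):
        patch = resp[r - 1 : r + 2, c - 1 : c + 2]
        w = np.clip(patch - mu_r, 0.0, None)
        if w.sum() <= 0:
            dy = dx = 0.0
        else:
            gy, gx = np.mgrid[-1:2, -1:2]
            dy = float((w * gy).sum() / w.sum())
            dx = float((w * gx).sum() / w.sum())
        peak = float(img[r, c])
        if peak <= mu_raw:
            continue  # filtered-domain maximum with no raw-intensity excess
        records.append(
            dict(
                image_id=image_id,
                channel=channel,
                x_um=(c + dx) * pixel_size_um,
                y_um=(r + dy) * pixel_size_um,
                row=int(r),
                col=int(c),
                peak_intensity=peak,
                background_local=mu_raw,
            )
        )
    det = pd.DataFrame(records, columns=DETECTION_COLUMNS)
    if len(det):
        det = det.sort_values(
            ["peak_intensity", "row", "col"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return det


def detect_stack(
    stack: np.ndarray,
    params: DetectionParams,
    pixel_size_um: float,
    image_id: str,
) -> pd.DataFrame:
    """Run :func:`detect_spots` on every channel of a (C, H, W) stack."""
    parts = [
        detect_spots(stack[c], params, pixel_size_um, image_id=image_id, channel=c)
        for c in range(stack.shape[0])
    ]
    return concat_nonempty(parts, DETECTION_COLUMNS)


def concat_nonempty(parts: list[pd.DataFrame], columns: list[str]) -> pd.DataFrame:
    """Concatenate frames, ignoring empty ones (keeps dtypes clean)."""
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame(columns=columns)
    return pd.concat(parts, ignore_index=True)
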