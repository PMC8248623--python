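"""Substrate deformation from bead-image pairs: drift correction and PIV.

The global stage drift between the tensed and relaxed exposure is first
estimated with sub-pixel precision by upsampled phase correlation of the
whole images; the tensed image is shifted back and both images are cropped
to the common field of view.

The deformation field is then measured by windowed cross-correlation
(PIV): for each interrogation window the zero-mean normalized cross-
correlation with the corresponding relaxed window is computed over all
integer shifts, the integer peak is refined to sub-pixel accuracy by a
three-point Gaussian fit along each axis, and vectors whose correlation
signal-to-noise ratio (highest peak over the second-highest peak outside a
2 px exclusion zone) falls below a threshold are replaced by the local
mean of their valid neighbors on the deformation grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import fourier_shift
from scipy.signal import fftconvolve
from skimage.registration import phase_cross_correlation

from .fields import ImagePair, VectorField2D

__all__ = ["PIVParams", "correct_drift", "compute_deformation"]

logger = logging.getLogger(__name__)

#: exclusion radius (correlation-matrix px, Chebyshev) around the first
#: peak when searching for the second peak of the SNR estimate
_SNR_EXCLUSION_PX = 2


@dataclass(frozen=True)
class PIVParams:
    """PIV settings.

    window_size        : interrogation window edge in px (e.g. 50).
    overlap            : window overlap in px; grid step = window - overlap.
    snr_threshold      : peak-to-second-peak ratio below which a vector is
                         rejected (1.03 by default).
    replacement_radius : Chebyshev radius, in deformation-grid points,
                         within which valid neighbors are averaged to
                         replace a rejected vector.
    """

    window_size: int = 50
    overlap: int = 25
    snr_threshold: float = 1.03
    replacement_radius: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.window_size:
            raise ValueError("need 0 <= overlap < window_size")
        if self.snr_threshold < 1:
            raise ValueError("snr_threshold must be >= 1")
        if self.replacement_radius < 1:
            raise ValueError("replacement_radius must be >= 1")

    @property
    def step(self) -> int:
        return self.window_size - self.overlap


def correct_drift(pair: ImagePair) -> tuple[ImagePair, np.ndarray]:
    """Estimate and remove global drift between the tensed and relaxed image.

    Returns the corrected pair (tensed image shifted onto the relaxed
    frame, both cropped to the overlapping field of view) and the drift as
    ``(drift_row, drift_col)`` in px — the sub-pixel displacement of the
    tensed image relative to the relaxed one.
    """
    tensed, relaxed = pair.tensed, pair.relaxed
    if tensed.std() == 0 or relaxed.std() == 0:
        raise ValueError("no texture for registration (constant image)")
    shift, _, _ = phase_cross_correlation(
        relaxed, tensed, upsample_factor=100, normalization=None
    )
    drift = -np.asarray(shift, dtype=float)  # tensed relative to relaxed
    if np.allclose(drift, 0.0):
        return ImagePair(tensed.copy(), relaxed.copy(), pair.pixel_size), drift
    aligned = np.fft.ifftn(fourier_shift(np.fft.fftn(tensed), shift)).real
    # crop the rows/cols that wrapped around during the shift
    r, c = int(np.ceil(abs(drift[0]))), int(np.ceil(abs(drift[1])))
    rows = slice(r, None) if drift[0] < 0 else slice(None, tensed.shape[0] - r or None)
    cols = slice(c, None) if drift[1] < 0 else slice(None, tensed.shape[1] - c or None)
    return (
        ImagePair(aligned[rows, cols], relaxed[rows, cols], pair.pixel_size),
        drift,
    )


def _gauss_subpixel(cm1: float, c0: float, cp1: float) -> float:
    """Three-point sub-pixel peak offset; Gaussian fit, parabolic fallback."""
    if cm1 > 0 and c0 > 0 and cp1 > 0:
        lm1, l0, lp1 = np.log(cm1), np.log(c0), np.log(cp1)
    else:
        lm1, l0, lp1 = cm1, c0, cp1
    denom = 2 * lm1 - 4 * l0 + 2 * lp1
    if denom == 0:
        return 0.0
    return float((lm1 - lp1) / denom)


def _window_displacement(
    w1: np.ndarray, w2: np.ndarray, snr_exclusion: int = _SNR_EXCLUSION_PX
) -> tuple[float, float, float]:
    """Displacement (dx, dy) of window w1 relative to w2, plus peak SNR."""
    a = w1 - w1.mean()
    b = w2 - w2.mean()
    norm = np.sqrt((a**2).sum() * (b**2).sum())
    if norm == 0:
        return np.nan, np.nan, 0.0
    corr = fftconvolve(a, b[::-1, ::-1], mode="full") / norm
    n = w1.shape[0]
    # compensate the triangular overlap taper of the full correlation (it
    # biases the sub-pixel fit toward zero) and only trust displacements up
    # to half a window, where enough pixels overlap
    lags = np.arange(corr.shape[0]) - (n - 1)
    overlap = np.maximum(n - np.abs(lags), 1) / n
    corr = corr / np.outer(overlap, overlap)
    valid = np.abs(lags) <= n // 2
    search = np.where(valid[:, None] & valid[None, :], corr, -np.inf)
    peak = np.unravel_index(np.argmax(search), corr.shape)
    # second peak outside a Chebyshev neighborhood of the first
    masked = search.copy()
    r0 = max(peak[0] - snr_exclusion, 0)
    c0 = max(peak[1] - snr_exclusion, 0)
    masked[r0 : peak[0] + snr_exclusion + 1, c0 : peak[1] + snr_exclusion + 1] = -np.inf
    second = masked.max()
    snr = np.inf if (not np.isfinite(second) or second <= 0) else corr[peak] / second
    dy = float(peak[0] - (n - 1))
    dx = float(peak[1] - (n - 1))
    if 0 < peak[0] < corr.shape[0] - 1:
        dy += _gauss_subpixel(
            corr[peak[0] - 1, peak[1]], corr[peak], corr[peak[0] + 1, peak[1]]
        )
    if 0 < peak[1] < corr.shape[1] - 1:
        dx += _gauss_subpixel(
            corr[peak[0], peak[1] - 1], corr[peak], corr[peak[0], peak[1] + 1]
        )
    return dx, dy, float(snr)


def _replace_outliers(
    vx: np.ndarray, vy: np.ndarray, invalid: np.ndarray, radius: int
) -> int:
    """In-place replacement of invalid vectors by local means; returns count."""
    n_replaced = int(invalid.sum())
    todo = invalid.copy()
    vx[todo] = np.nan
    vy[todo] = np.nan
    while todo.any():
        progress = False
        for r, c in zip(*np.nonzero(todo)):
            rs = slice(max(r - radius, 0), r + radius + 1)
            cs = slice(max(c - radius, 0), c + radius + 1)
            neigh = vx[rs, cs]
            good = np.isfinite(neigh)
            if good.any():
                vx[r, c] = np.nanmean(vx[rs, cs])
                vy[r, c] = np.nanmean(vy[rs, cs])
                todo[r, c] = False
                progress = True
        if not progress:
            # isolated cluster larger than the radius: grow the search
            radius += 1
    return n_replaced


def compute_deformation(
    pair: ImagePair, params: PIVParams | None = None, full_output: bool = False
):
    """PIV deformation field of a (drift-corrected) image pair, in um.

    Interrogation windows are laid on a regular grid with step
    ``window_size - overlap``; border regions not covered by a full window
    carry no vector.  Returns a :class:`VectorField2D` whose
    ``origin_offset`` is the image position of the first window center.
    With ``full_output=True`` additionally returns a dict with the SNR map
    and the number of replaced vectors.
    """
    params = params or PIVParams()
    ws, step = params.window_size, params.step
    h, w = pair.shape
    if ws > h or ws > w:
        raise ValueError("PIV window larger than the image")
    r0s = np.arange(0, h - ws + 1, step)
    c0s = np.arange(0, w - ws + 1, step)
    vx = np.zeros((len(r0s), len(c0s)))
    vy = np.zeros_like(vx)
    snr = np.zeros_like(vx)
    for i, r0 in enumerate(r0s):
        for j, c0 in enumerate(c0s):
            dx, dy, s = _window_displacement(
                pair.tensed[r0 : r0 + ws, c0 : c0 + ws],
                pair.relaxed[r0 : r0 + ws, c0 : c0 + ws],
            )
            vx[i, j], vy[i, j], snr[i, j] = dx, dy, s
    invalid = ~np.isfinite(vx) | (snr < params.snr_threshold)
    if invalid.all():
        raise ValueError("deformation field unrecoverable: all vectors invalid")
    n_replaced = _replace_outliers(vx, vy, invalid, params.replacement_radius)
    if n_replaced:
        logger.info("replaced %d/%d low-SNR deformation vectors", n_replaced, vx.size)
    vx *= pair.pixel_size
    vy *= pair.pixel_size
    center = (ws - 1) / 2.0
    field = VectorField2D(
        vx, vy,
        grid_spacing=step * pair.pixel_size,
        origin_offset=(c0s[0] + center, r0s[0] + center),
    )
    if full_output:
        return field, {"snr": snr, "n_replaced": n_replaced}
    return field
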