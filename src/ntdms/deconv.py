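"""Profile-spectrum enhancement before envelope detection.

Two workflows: the *extensive* path sharpens the profile with a windowed
Richardson-Lucy deconvolution (Gaussian point spread function whose sigma
follows the m/z-dependent peak width of FT analyzers), and the *rapid* path
picks centroids directly with continuous-wavelet-transform ridge detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .msio import CentroidPeak, ProfileSpectrum


@dataclass(frozen=True)
class PsfModel:
    """Gaussian peak-shape model: sigma(m/z) = sigma_ref * (m/z / mz_ref)**exponent.

    The default exponent 1.5 follows from FT resolution scaling as
    m/z**-0.5, so the absolute peak width grows as m/z**1.5.
    """

    sigma_ref: float
    mz_ref: float = 200.0
    exponent: float = 1.5

    def __post_init__(self):
        if self.sigma_ref <= 0:
            raise ValueError("sigma_ref must be > 0")

    def sigma(self, mz):
        return self.sigma_ref * (np.asarray(mz) / self.mz_ref) ** self.exponent

    @classmethod
    def from_resolution(cls, resolution: float = 240_000.0, mz_ref: float = 200.0):
        """PSF from a stated FWHM resolving power at ``mz_ref``."""
        fwhm = mz_ref / resolution
        return cls(sigma_ref=fwhm / 2.3548200450309493, mz_ref=mz_ref)


def _gaussian_kernel(sigma_pts: float) -> np.ndarray:
    half = max(1, int(np.ceil(4 * sigma_pts)))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma_pts) ** 2)
    return k / k.sum()


def _rl_iterate(data: np.ndarray, kernel: np.ndarray, n_iter: int, rtol: float) -> np.ndarray:
    """Multiplicative Richardson-Lucy updates; flux-conserving, non-negative."""
    d = np.clip(data, 0.0, None)
    if d.sum() == 0:
        return d
    u = d.copy()
    krev = kernel[::-1]
    eps = 1e-12 * d.max()
    for _ in range(n_iter):
        conv = fftconvolve(u, kernel, mode="same")
        ratio = d / np.maximum(conv, eps)
        u_new = u * fftconvolve(ratio, krev, mode="same")
        change = np.abs(u_new - u).sum() / max(u.sum(), eps)
        u = u_new
        if change < rtol:
            break
    np.clip(u, 0.0, None, out=u)
    s = u.sum()
    if s > 0:
        u *= d.sum() / s
    return u


def richardson_lucy_deconvolve(
    s: ProfileSpectrum,
    psf: PsfModel,
    window_width: float = 100.0,
    n_iter: int = 50,
    rtol: float = 1e-5,
) -> ProfileSpectrum:
    """Windowed Richardson-Lucy deconvolution of a profile spectrum.

    The spectrum is processed in windows of ``window_width`` Th (10% overlap,
    linear cross-fade blending) so the Gaussian kernel can track the
    m/z-dependent peak width; each window conserves total intensity.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if len(s) == 0:
        raise ValueError("empty spectrum")
    mz, inten = s.mz, s.intensity
    out = np.zeros_like(inten)
    weight = np.zeros_like(inten)
    overlap = 0.1 * window_width
    lo = mz[0]
    while lo < mz[-1] + 1e-9:
        hi = lo + window_width
        i, j = np.searchsorted(mz, [lo - overlap, hi + overlap])
        if j - i >= 3:
            sub_mz = mz[i:j]
            dx = np.median(np.diff(sub_mz))
            sigma = float(psf.sigma(0.5 * (sub_mz[0] + sub_mz[-1])))
            if window_width < 10 * sigma:
                raise ValueError(
                    f"window width {window_width} Th narrower than 10 sigma "
                    f"({10 * sigma:.3f} Th)"
                )
            sigma_pts = max(sigma / dx, 0.5)
            kernel = _gaussian_kernel(sigma_pts)
            dec = _rl_iterate(inten[i:j], kernel, n_iter, rtol)
            # linear cross-fade: full weight in the core, ramps in the overlaps
            ramp_lo = np.clip((sub_mz - (lo - overlap)) / (2 * overlap), 0, 1)
            ramp_hi = np.clip(((hi + overlap) - sub_mz) / (2 * overlap), 0, 1)
            if lo <= mz[0]:
                ramp_lo[:] = 1.0  # no left neighbour
            if hi >= mz[-1]:
                ramp_hi[:] = 1.0  # no right neighbour
            w = np.minimum(ramp_lo, ramp_hi)
            out[i:j] += w * dec
            weight[i:j] += w
        lo = hi
    filled = weight > 0
    out[filled] /= weight[filled]
    out[~filled] = inten[~filled]
    return ProfileSpectrum(mz=mz.copy(), intensity=out, metadata=dict(s.metadata))


def _mexican_hat(sigma_pts: float) -> np.ndarray:
    half = max(2, int(np.ceil(5 * sigma_pts)))
    x = np.arange(-half, half + 1, dtype=float)
    a = x / sigma_pts
    k = (1 - a**2) * np.exp(-0.5 * a**2)
    return k / np.sqrt(sigma_pts)


def cwt_pick_peaks(
    s: ProfileSpectrum,
    snr_min: float = 3.0,
    psf: PsfModel | None = None,
    n_scales: int = 6,
    min_ridge_len: int = 2,
) -> list[CentroidPeak]:
    """Continuous-wavelet-transform ridge peak picking.

    Mexican-hat responses are computed at scales spanning the PSF widths
    across the spectrum; local maxima are linked into ridge lines across
    scales and a ridge is kept when it persists over ``min_ridge_len``
    scales with best response above ``snr_min`` times the noise (median
    absolute response at the smallest scale).  Centroids are
    intensity-weighted means over the apex region of the raw profile.
    """
    if len(s) == 0:
        raise ValueError("empty spectrum")
    if psf is None:
        psf = PsfModel.from_resolution()
    mz, inten = s.mz, s.intensity
    if len(mz) < 5 or inten.max() <= 0:
        return []
    dx = np.median(np.diff(mz))
    smin = max(float(psf.sigma(mz[0])) / dx, 1.0)
    smax = max(float(psf.sigma(mz[-1])) / dx, smin * 1.5)
    scales = np.geomspace(smin, smax, n_scales)
    rows = []
    for sc in scales:
        resp = fftconvolve(inten, _mexican_hat(sc), mode="same")
        rows.append(resp)
    cwt = np.array(rows)
    # floor the noise estimate so numerically-zero regions of noiseless
    # spectra cannot seed ghost ridges
    noise = max(float(np.median(np.abs(cwt[0]))), 1e-9 * float(cwt.max()), 1e-30)

    # local maxima per scale row; noise maxima are pruned before linking
    floor = 0.5 * snr_min * noise
    maxima = []
    for r in range(n_scales):
        row = cwt[r]
        idx = np.flatnonzero((row[1:-1] > row[:-2]) & (row[1:-1] >= row[2:])) + 1
        maxima.append(idx[row[idx] > floor])

    # greedy ridge linking from the smallest scale upward
    ridges = [[(0, i)] for i in maxima[0]]
    open_ridges = list(range(len(ridges)))
    for r in range(1, n_scales):
        cand = maxima[r]
        used = np.zeros(len(cand), dtype=bool)
        still_open = []
        for ri in open_ridges:
            last_r, last_i = ridges[ri][-1]
            if r - last_r > 1:
                continue
            win = scales[r] * 2
            j = np.searchsorted(cand, [last_i - win, last_i + win])
            best, bestdist = -1, None
            for ci in range(j[0], j[1]):
                if used[ci]:
                    continue
                dist = abs(int(cand[ci]) - last_i)
                if bestdist is None or dist < bestdist:
                    best, bestdist = ci, dist
            if best >= 0:
                used[best] = True
                ridges[ri].append((r, int(cand[best])))
                still_open.append(ri)
        open_ridges = still_open
        for ci in np.flatnonzero(~used):
            ridges.append([(r, int(cand[ci]))])

    peaks: list[CentroidPeak] = []
    seen: set[int] = set()
    for ridge in ridges:
        if len(ridge) < min_ridge_len:
            continue
        best_r, best_i = max(ridge, key=lambda t: cwt[t[0], t[1]])
        if cwt[best_r, best_i] / noise < snr_min:
            continue
        apex = ridge[0][1]  # position at the smallest scale on the ridge
        if apex in seen:
            continue
        seen.add(apex)
        sigma_pts = scales[ridge[0][0]]
        half = max(1, int(round(sigma_pts)))
        i0, i1 = max(0, apex - half), min(len(mz), apex + half + 1)
        w = inten[i0:i1]
        if w.sum() <= 0 or inten[apex] < 1e-6 * inten.max():
            continue
        centroid = float(np.average(mz[i0:i1], weights=w))
        peaks.append(
            CentroidPeak(
                mz=centroid,
                intensity=float(inten[apex]) if inten[apex] > 0 else float(w.max()),
                width_sigma=float(sigma_pts * dx),
            )
        )
    peaks.sort(key=lambda p: p.mz)
    return peaks
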