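"""Preprocessing ahead of reconstruction and fitting.

* HSVD water removal: the FID is modelled as a sum of damped complex
  exponentials recovered from a rank-truncated Hankel matrix (state-space /
  shift-invariance method); components falling inside the water band are
  re-fit by linear least squares and subtracted.
* Simplified water-reference estimators: a per-voxel weighted phase-slope
  fit for the B0 map and smoothed-image ratios for coil sensitivities.
  Both are deliberately simple; externally computed maps can always be
  supplied to the reconstruction instead.
* Backward linear prediction extends an FID acquired from TE > 0 back to
  t = 0, removing first-order spectral phase.

All operations here are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import hankel
from scipy.ndimage import gaussian_filter

__all__ = [
    "FieldMap",
    "CoilMaps",
    "hsvd_water_removal",
    "hsvd_components",
    "estimate_b0_map",
    "estimate_coil_maps",
    "backward_predict_fid",
]


@dataclass
class FieldMap:
    """Per-voxel frequency offset (Hz) with a validity mask."""

    b0_hz: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.b0_hz[self.valid_mask])):
            raise ValueError("non-finite field map values inside the mask")


@dataclass
class CoilMaps:
    """Complex coil sensitivities, RSS-normalized to 1 inside the mask."""

    sensitivities: np.ndarray  # (C, n, n)
    mask: np.ndarray  # (n, n) bool

    def __post_init__(self):
        rss = np.sqrt(np.sum(np.abs(self.sensitivities) ** 2, axis=0))
        inside = rss[self.mask]
        if inside.size and (inside.min() < 1 - 1e-6 or inside.max() > 1 + 1e-6):
            raise ValueError("coil maps are not RSS-normalized inside the mask")


def hsvd_components(fid: np.ndarray, sbw: float, model_order: int = 25):
    """Damped-exponential decomposition of an FID.

    Returns (freqs_hz, dampings_per_s, amplitudes): the poles come from the
    shift-invariance of the rank-truncated Hankel signal subspace, the
    complex amplitudes from a linear least-squares re-fit.
    """
    x = np.asarray(fid, complex).ravel()
    T = x.size
    if model_order >= T / 2:
        raise ValueError("model_order must be smaller than half the FID length")
    dt = 1.0 / sbw
    rows = int(np.ceil(T / 2))
    H = hankel(x[:rows], x[rows - 1:])
    Uk, sv, _ = np.linalg.svd(H, full_matrices=False)
    # cap the order at the numerically significant subspace; spurious poles
    # from a rank-deficient Hankel make the amplitude refit ill-conditioned
    order = min(model_order, int(np.sum(sv > 1e-10 * sv[0])))
    Uk = Uk[:, :order]
    # shift method: Uk_top Z = Uk_bottom
    Z = np.linalg.lstsq(Uk[:-1], Uk[1:], rcond=None)[0]
    z = np.linalg.eigvals(Z)
    z = z[np.abs(z) > 1e-12]
    freqs = np.angle(z) / (2 * np.pi * dt)
    damp = -np.log(np.abs(z)) / dt
    # amplitude re-fit on the full FID
    tt = np.arange(T)
    V = z[None, :] ** tt[:, None]
    amps, *_ = np.linalg.lstsq(V, x, rcond=None)
    cond = np.linalg.cond(V)
    if cond > 1e10:
        warnings.warn("ill-conditioned HSVD amplitude fit; subtraction is "
                      "best-effort", RuntimeWarning)
    return freqs, damp, amps, z


def hsvd_water_removal(fid: np.ndarray, sbw: float,
                       water_band: tuple[float, float] = (-60.0, 60.0),
                       model_order: int = 25) -> np.ndarray:
    """Subtract HSVD components whose frequency falls inside the water band.

    ``water_band`` is given in Hz relative to the carrier; the default
    +/- 60 Hz around the (water) carrier removes the residual water peak
    while leaving metabolite resonances untouched.  Output length equals the
    input length.
    """
    x = np.asarray(fid, complex).ravel()
    freqs, _, amps, z = hsvd_components(x, sbw, model_order)
    lo, hi = min(water_band), max(water_band)
    in_band = (freqs >= lo) & (freqs <= hi)
    if not in_band.any():
        return x.copy()
    tt = np.arange(x.size)
    water = (z[None, in_band] ** tt[:, None]) @ amps[in_band]
    return x - water


def estimate_b0_map(water_ref_images: np.ndarray, times: np.ndarray,
                    magnitude_threshold: float = 0.05) -> FieldMap:
    """Field map from a water-dominated complex image time series.

    Per voxel, the frequency is the slope of the temporally unwrapped phase
    versus time, fitted by magnitude-weighted least squares.  Voxels below
    ``magnitude_threshold`` of the peak magnitude, and voxels whose fitted
    offset approaches the spectral aliasing limit (0.45 / dt), are excluded
    from ``valid_mask``.
    """
    imgs = np.asarray(water_ref_images, complex)
    t = np.asarray(times, float)
    if imgs.shape[-1] < 3 or t.size < 3:
        raise ValueError("need at least 3 time points to fit a field map")
    phase = np.unwrap(np.angle(imgs), axis=-1)
    wgt = np.abs(imgs)
    sw = np.sum(wgt, axis=-1)
    sw = np.where(sw > 0, sw, 1.0)
    tm = np.sum(wgt * t, axis=-1) / sw
    pm = np.sum(wgt * phase, axis=-1) / sw
    cov = np.sum(wgt * (t - tm[..., None]) * (phase - pm[..., None]), axis=-1)
    var = np.sum(wgt * (t - tm[..., None]) ** 2, axis=-1)
    slope = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)
    b0 = slope / (2 * np.pi)
    mag = np.mean(wgt, axis=-1)
    mask = mag > magnitude_threshold * mag.max()
    dt = float(np.median(np.diff(t)))
    alias_limit = 0.45 / dt
    mask &= np.abs(b0) < alias_limit
    return FieldMap(b0_hz=np.where(mask, b0, 0.0), valid_mask=mask)


def estimate_coil_maps(water_ref_first_point: np.ndarray,
                       smoothing_fwhm: float = 3.0,
                       mask_threshold: float = 0.02) -> CoilMaps:
    """Coil sensitivities as smoothed coil images over their smoothed RSS.

    A lightweight stand-in for subspace calibration: sensitivity variations
    are smooth, so low-pass filtering each complex coil image and dividing
    by the root-sum-of-squares recovers relative sensitivities up to a
    common real scale.  RSS is exactly 1 inside the mask by construction.
    """
    imgs = np.asarray(water_ref_first_point, complex)
    if imgs.ndim != 3:
        raise ValueError("expected (coil, n, n) first-time-point images")
    sigma = smoothing_fwhm / 2.3548
    sm = np.empty_like(imgs)
    for c in range(imgs.shape[0]):
        sm[c] = gaussian_filter(imgs[c].real, sigma) + 1j * gaussian_filter(imgs[c].imag, sigma)
    rss = np.sqrt(np.sum(np.abs(sm) ** 2, axis=0))
    mask = rss > mask_threshold * rss.max()
    safe = np.where(rss > 0, rss, 1.0)
    sens = np.where(mask[None], sm / safe[None], 0.0)
    return CoilMaps(sensitivities=sens, mask=mask)


def backward_predict_fid(fid: np.ndarray, n_back: int, lp_order: int = 8,
                         min_root_radius: float = 0.3) -> np.ndarray:
    """Extrapolate an FID backwards to t = 0 by backward linear prediction.

    Fits coefficients a with  x[n] = sum_k a_k x[n+k]  on the early FID and
    prepends ``n_back`` extrapolated samples, so that spectra computed from
    the extended FID need no first-order phase correction.  Roots of the
    prediction polynomial decaying implausibly fast (|root| below
    ``min_root_radius``, typically noise) are reflected back to the stable
    region with a warning, since they blow up under backward recursion.
    """
    x = np.asarray(fid, complex).ravel()
    if n_back == 0:
        return x.copy()
    if n_back < 0:
        raise ValueError("n_back must be >= 0")
    if lp_order >= x.size / 3:
        raise ValueError("lp_order must be smaller than a third of the FID length")
    p = lp_order
    rows = x.size - p
    A = np.column_stack([x[k + 1: k + 1 + rows] for k in range(p)])
    a, *_ = np.linalg.lstsq(A, x[:rows], rcond=None)
    # characteristic roots of x[n] = sum a_k x[n+k] (in the forward variable)
    poly = np.concatenate([[1.0], -a])  # coefficients of 1 - sum a_k zeta^k
    roots = np.roots(poly[::-1])  # signal poles zeta; zeta^{-m} grows backwards
    bad = np.abs(roots) < min_root_radius
    if bad.any():
        warnings.warn("unstable backward-prediction roots reflected into the "
                      "stable region", RuntimeWarning)
        roots[bad] = roots[bad] / np.abs(roots[bad]) * min_root_radius
        poly_new = np.poly(roots)
        poly_new = poly_new / poly_new[-1]  # restore unit constant term
        a = -poly_new[::-1][1:]
    ext = np.empty(n_back + x.size, complex)
    ext[n_back:] = x
    for m in range(n_back - 1, -1, -1):
        ext[m] = np.dot(a, ext[m + 1: m + 1 + p])
    return ext
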