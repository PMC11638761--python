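"""Quantification of reconstructed spectra and evaluation metrics.

Metabolite maps come from a linear-combination fit of each voxel FID
against the basis FIDs (real-coefficient least squares, optionally
non-negative), referenced to the water amplitude and expressed in
institutional units (I.U.; the absolute scale constant is 1, so only
ratios are meaningful).  Evaluation metrics: masked SSIM (Gaussian window,
standard stabilization constants), masked Pearson correlation, spectral
SNR/FWHM, and coefficients of variation across repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .phantom import SpectralBasis

__all__ = [
    "MetaboliteMaps",
    "fit_basis_maps",
    "ssim",
    "pearson_in_mask",
    "spectral_snr_fwhm",
    "cov_by_region",
    "quality_mask",
]


@dataclass
class MetaboliteMaps:
    """Per-metabolite amplitude maps in institutional units."""

    maps: dict[str, np.ndarray]
    residual: np.ndarray
    mask: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


def _basis_matrix(basis: SpectralBasis, times: np.ndarray, t2star: float,
                  names: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    names = names or basis.names
    B = np.column_stack([basis.fid(m, times, t2star) for m in names])
    return B, names


def fit_basis_maps(
    rho: np.ndarray,
    basis: SpectralBasis,
    times: np.ndarray,
    t2star: float,
    water_ref_amp: np.ndarray | float = 1.0,
    nonneg: bool = False,
    mask: np.ndarray | None = None,
    metabolites: list[str] | None = None,
    iu_scale: float = 1.0,
) -> MetaboliteMaps:
    """Linear-combination fit of voxel FIDs against basis FIDs.

    Solves per voxel  min_c || fid - sum_m c_m b_m(t) ||^2  over real
    coefficients (both real and imaginary parts of the data enter the fit),
    optionally with c_m >= 0.  Maps are divided by ``water_ref_amp`` to give
    institutional units.
    """
    rho = np.asarray(rho, complex)
    n0, n1, T = rho.shape
    t = np.asarray(times, float)
    B, names = _basis_matrix(basis, t, t2star, metabolites)
    # collinearity check
    Bn = B / np.linalg.norm(B, axis=0, keepdims=True)
    G = np.abs(Bn.conj().T @ Bn)
    bad = [(names[i], names[j]) for i in range(len(names))
           for j in range(i + 1, len(names)) if G[i, j] > 0.9999]
    if bad:
        raise ValueError(f"rank-deficient basis; collinear pairs: {bad}")
    Br = np.vstack([B.real, B.imag])  # (2T, M) real design
    if mask is None:
        mask = np.ones((n0, n1), bool)
    X = rho.reshape(-1, T)[mask.ravel()]
    Y = np.hstack([X.real, X.imag]).T  # (2T, Nmask)
    if nonneg:
        from scipy.optimize import nnls
        coefs = np.empty((len(names), Y.shape[1]))
        for v in range(Y.shape[1]):
            coefs[:, v] = nnls(Br, Y[:, v])[0]
    else:
        coefs, *_ = np.linalg.lstsq(Br, Y, rcond=None)
    resid = np.linalg.norm(Y - Br @ coefs, axis=0)

    wref = np.broadcast_to(np.asarray(water_ref_amp, float), (n0, n1))
    maps: dict[str, np.ndarray] = {}
    for i, name in enumerate(names):
        full = np.full((n0, n1), np.nan)
        full[mask] = coefs[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            full = iu_scale * full / np.where(wref > 0, wref, np.nan)
        maps[name] = full
    res_map = np.full((n0, n1), np.nan)
    res_map[mask] = resid
    return MetaboliteMaps(maps=maps, residual=res_map, mask=mask)


def ssim(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None,
         window_sigma: float = 1.5) -> float:
    """Mean local SSIM of ``a`` against the reference ``b`` over the mask.

    Gaussian window (sigma in pixels) and the standard stabilization
    constants K1 = 0.01, K2 = 0.03; the reference image defines the dynamic
    range.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if mask is None:
        mask = np.ones(a.shape, bool)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    rng_b = float(b.max() - b.min())
    _, smap = structural_similarity(
        a, b, gaussian_weights=True, sigma=window_sigma,
        use_sample_covariance=False, data_range=rng_b if rng_b > 0 else 1.0,
        K1=0.01, K2=0.03, full=True,
    )
    return float(np.mean(smap[mask]))


def pearson_in_mask(a: np.ndarray, b: np.ndarray,
                    mask: np.ndarray | None = None) -> float:
    """Pearson correlation of masked voxels; NaN if either side is constant."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if mask is None:
        mask = np.ones(a.shape, bool)
    x, y = a[mask], b[mask]
    if x.size < 3:
        raise ValueError("need at least 3 voxels in the mask")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def spectral_snr_fwhm(
    spectrum: np.ndarray,
    freqs: np.ndarray,
    signal_band: tuple[float, float],
    noise_band: tuple[float, float],
) -> tuple[float, float]:
    """SNR and line width of the tallest peak in ``signal_band``.

    SNR = max |spectrum| inside the signal band over the standard deviation
    of the real part inside the noise band; FWHM (in the frequency unit of
    ``freqs``) by linear interpolation of the half-maximum crossings around
    the peak.
    """
    spec = np.asarray(spectrum)
    f = np.asarray(freqs, float)
    sig = (f >= min(signal_band)) & (f <= max(signal_band))
    noi = (f >= min(noise_band)) & (f <= max(noise_band))
    if not sig.any() or not noi.any():
        raise ValueError("empty signal or noise band")
    if (sig & noi).any():
        raise ValueError("signal and noise bands must be disjoint")
    mag = np.abs(spec)
    noise_std = float(np.std(np.real(spec[noi])))
    peak_val = float(mag[sig].max())
    snr = peak_val / noise_std if noise_std > 0 else float("inf")

    order = np.argsort(f)
    f_s, m_s = f[order], mag[order]
    ipk = int(np.argmax(np.where((f_s >= min(signal_band)) & (f_s <= max(signal_band)),
                                 m_s, -np.inf)))
    half = m_s[ipk] / 2.0

    def crossing(idx_range):
        prev = ipk
        for i in idx_range:
            if m_s[i] < half:
                frac = (m_s[prev] - half) / (m_s[prev] - m_s[i])
                return f_s[prev] + frac * (f_s[i] - f_s[prev])
            prev = i
        return f_s[idx_range[-1]] if len(idx_range) else f_s[ipk]

    hi = crossing(range(ipk + 1, len(f_s)))
    lo = crossing(range(ipk - 1, -1, -1))
    return snr, float(abs(hi - lo))


def cov_by_region(
    maps_list: list[MetaboliteMaps],
    region_labels: np.ndarray,
    ddof: int = 0,
) -> dict[str, dict[int, float]]:
    """Coefficient of variation of region-mean amplitudes across repetitions.

    For each region label (> 0) and metabolite, the mean amplitude inside
    the region is taken per repetition; COV = std/mean across repetitions
    (population std by default).  A region with zero mean yields NaN.
    """
    if len(maps_list) < 2:
        raise ValueError("need at least 2 repetitions")
    labels = np.asarray(region_labels)
    out: dict[str, dict[int, float]] = {}
    names = maps_list[0].maps.keys()
    for name in names:
        out[name] = {}
        for lab in np.unique(labels):
            if lab <= 0:
                continue
            vals = np.array([np.nanmean(m.maps[name][labels == lab])
                             for m in maps_list])
            mu = vals.mean()
            out[name][int(lab)] = float(vals.std(ddof=ddof) / mu) if mu != 0 else float("nan")
    return out


def quality_mask(pseudo_crlb: np.ndarray, fwhm_ppm: np.ndarray, snr: np.ndarray,
                 crlb_max: float = 20.0, fwhm_max: float = 0.07,
                 snr_min: float = 5.0) -> np.ndarray:
    """Good-quality voxel predicate: pseudo-CRLB < 20%, FWHM < 0.07 ppm,
    SNR > 5.  The pseudo-CRLB is a simplified residual-based approximation
    of a fit uncertainty, not a full Fisher-information bound."""
    return (pseudo_crlb < crlb_max) & (fwhm_ppm < fwhm_max) & (snr > snr_min)
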