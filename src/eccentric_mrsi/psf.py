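"""Point-spread-function analysis of circular sampling plans.

The PSF of a plan is the density-compensated adjoint non-uniform Fourier
transform of a unit point source at the grid origin:

    PSF(r) = sum_j w_j exp(-i 2 pi k_j . r),

with w_j the Voronoi cell areas of the samples.  Incoherent (noise-like)
sidelobes under undersampling are what make a trajectory suited to
compressed sensing; the two scalar metrics below (peak sidelobe and
sidelobe energy outside a main-lobe exclusion disc) quantify that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .operators import NUFT
from .trajectories import TrajectoryPlan, sample_points, voronoi_density

__all__ = ["PSFImage", "PSFMetrics", "compute_psf", "psf_metrics"]


@dataclass
class PSFImage:
    values: np.ndarray  # complex, (n, n), unit peak
    peak_location: tuple[int, int]
    normalization: complex  # divide raw PSF by this to get unit peak

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class PSFMetrics:
    fwhm: float  # pixels
    peak_sidelobe: float  # relative to unit peak
    sidelobe_energy: float  # fraction of total |PSF|^2 outside exclusion


def compute_psf(plan: TrajectoryPlan, weights: np.ndarray | None = None) -> PSFImage:
    """PSF of a single-partition plan on its own image grid.

    Voronoi density-compensation weights are computed from the plan's sample
    cloud unless supplied explicitly.
    """
    kz = {c.kz_index for c in plan.circles}
    if len(kz) != 1:
        raise ValueError("PSF is defined per partition; got a multi-partition plan")
    pts = sample_points(plan).reshape(-1, 2)
    if weights is None:
        weights = voronoi_density(pts, clip_radius=plan.grid.kmax + plan.grid.dk / 2)
    nuft = NUFT(pts, plan.grid)
    img = nuft.adjoint(weights.astype(complex))
    peak = np.unravel_index(np.argmax(np.abs(img)), img.shape)
    norm = img[peak]
    return PSFImage(values=img / norm, peak_location=(int(peak[0]), int(peak[1])),
                    normalization=norm)


def _radial_profile(mag: np.ndarray, peak: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Radially binned mean magnitude (1-pixel bins) around the peak."""
    n0, n1 = mag.shape
    ii, jj = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    r = np.hypot(ii - peak[0], jj - peak[1]).ravel()
    v = mag.ravel()
    nbins = int(np.ceil(r.max())) + 1
    idx = np.minimum(r.astype(int), nbins - 1)
    sums = np.bincount(idx, weights=v, minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    prof = sums / np.maximum(counts, 1)
    radii = np.arange(nbins, dtype=float)
    return radii, prof


def psf_metrics(psf: PSFImage, exclusion_radius: float = 3.0) -> PSFMetrics:
    """Main-lobe FWHM plus sidelobe level/energy outside the exclusion disc.

    FWHM is found by linear interpolation of the first half-maximum crossing
    of the radial profile through the peak; the main lobe cannot be narrower
    than one pixel.
    """
    if exclusion_radius < 1:
        raise ValueError("exclusion_radius must be >= 1 pixel")
    mag = np.abs(psf.values)
    radii, prof = _radial_profile(mag, psf.peak_location)
    half = 0.5 * prof[0]
    fwhm = 1.0
    below = np.flatnonzero(prof < half)
    if below.size:
        j = below[0]
        if j == 0:
            fwhm = 1.0
        else:
            # linear interpolation between bins j-1 and j
            f = (prof[j - 1] - half) / (prof[j - 1] - prof[j])
            fwhm = max(1.0, 2.0 * (radii[j - 1] + f))
    n0, n1 = mag.shape
    ii, jj = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    r = np.hypot(ii - psf.peak_location[0], jj - psf.peak_location[1])
    outside = r > exclusion_radius
    peak_sidelobe = float(mag[outside].max()) if outside.any() else 0.0
    total = float(np.sum(mag**2))
    side_energy = float(np.sum(mag[outside] ** 2)) / total if total > 0 else 0.0
    return PSFMetrics(fwhm=float(fwhm), peak_sidelobe=peak_sidelobe,
                      sidelobe_energy=side_energy)
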