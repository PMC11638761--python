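"""Non-uniform Fourier encoding operators.

The forward model of one coil channel at spectral time t is

    s_{j,t} = sum_i  C(r_i) exp(i 2 pi b0(r_i) t) exp(i 2 pi k_j . r_i) rho(r_i, t),

a type-1 discrete non-uniform Fourier transform (positive exponent for
image -> k).  Because the image grid is a Cartesian product, each sample's
exponential factorizes as exp(i2pi kx x) exp(i2pi ky y); the transform is
therefore evaluated exactly with two BLAS matrix products per batch instead
of an approximate gridding kernel.  At the matrix sizes used here
(n <= 64, up to a few 10^4 samples) this is both exact and fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trajectories import GridSpec, TrajectoryPlan, sample_points, plan_sample_weights

__all__ = ["NUFT", "EncodingOperator", "hamming_weights", "apply_weighting",
           "nuft_forward", "nuft_adjoint"]


class NUFT:
    """Exact type-1/2 non-uniform Fourier transform on a centred grid.

    Parameters
    ----------
    k_points : (S, 2) array
        Sample coordinates in cycles/m.
    grid : GridSpec
        Image grid; coordinates r_i = (i - n/2) FoV / n.
    """

    def __init__(self, k_points: np.ndarray, grid: GridSpec):
        self.grid = grid
        self.k = np.asarray(k_points, dtype=float).reshape(-1, 2)
        r = grid.image_coords()
        # (S, n) separable phase factors, positive exponent (image -> k)
        self.Ax = np.exp(2j * math.pi * np.outer(self.k[:, 0], r))
        self.Ay = np.exp(2j * math.pi * np.outer(self.k[:, 1], r))

    @property
    def n_samples(self) -> int:
        return self.k.shape[0]

    def forward(self, image: np.ndarray) -> np.ndarray:
        """(n, n[, B]) image(s) -> (S[, B]) samples; exact Eq.-style sum."""
        n = self.grid.n_xy
        img = np.asarray(image)
        squeeze = img.ndim == 2
        x = img.reshape(n, n, -1)
        # sum_i,l Ax[s,i] Ay[s,l] x[i,l,b]
        tmp = np.tensordot(self.Ax, x, axes=(1, 0))  # (S, n, B)
        out = np.einsum("sl,slb->sb", self.Ay, tmp)
        return out[:, 0] if squeeze else out

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """(S[, B]) samples -> (n, n[, B]) image(s); conjugate-transpose."""
        n = self.grid.n_xy
        s = np.asarray(samples)
        squeeze = s.ndim == 1
        y = s.reshape(self.n_samples, -1)
        tmp = np.einsum("sl,sb->slb", self.Ay.conj(), y)  # (S, n, B)
        out = np.tensordot(self.Ax.conj(), tmp, axes=(0, 0))  # (n, n, B)
        return out[:, :, 0] if squeeze else out


def nuft_forward(image: np.ndarray, k_points: np.ndarray, grid: GridSpec) -> np.ndarray:
    """One-shot type-1 transform: image(s) on the grid -> samples at k_points."""
    return NUFT(k_points, grid).forward(image)


def nuft_adjoint(samples: np.ndarray, k_points: np.ndarray, grid: GridSpec) -> np.ndarray:
    """One-shot adjoint (type-2 conjugate) transform: samples -> grid image(s)."""
    return NUFT(k_points, grid).adjoint(samples)


def hamming_weights(k_points: np.ndarray, kmax: float) -> np.ndarray:
    """Hamming-shaped k-space weights w(k) = 0.54 + 0.46 cos(pi ||k||/kmax).

    Unity at the k-space centre, 0.08 at ||k|| = kmax; radii beyond kmax
    (possible up to kmax + dk/2) are clamped so the window stays monotone
    non-increasing.
    """
    k = np.asarray(k_points, dtype=float).reshape(-1, 2)
    r = np.minimum(np.hypot(k[:, 0], k[:, 1]), kmax)
    return 0.54 + 0.46 * np.cos(math.pi * r / kmax)


def apply_weighting(residual: np.ndarray, plan: TrajectoryPlan) -> np.ndarray:
    """Multiply per-sample residuals by the plan's Hamming window.

    ``residual`` has the sample axis second-to-last or is 1D of length S.
    """
    w = hamming_weights(sample_points(plan).reshape(-1, 2), plan.grid.kmax)
    res = np.asarray(residual)
    if res.ndim == 1:
        return res * w
    shape = [1] * res.ndim
    shape[-2] = w.size
    return res * w.reshape(shape)


@dataclass
class EncodingOperator:
    """Composed encoding W . F . C . B for the CS-SENSE-LR inverse problem.

    Holds the NUFT for the plan's sample locations, the coil sensitivities C
    (``None`` means a single unit coil), the per-voxel frequency-offset map
    b0 (Hz; ``None`` means on-resonance) and the Hamming data weights w(k).
    ``forward``/``adjoint`` implement F.C.B and its conjugate transpose; the
    weights are exposed separately (they enter the normal equations as w^2).
    """

    plan: TrajectoryPlan
    coil_maps: np.ndarray | None = None  # (C, n, n) complex
    b0_map: np.ndarray | None = None  # (n, n) Hz
    weighting: str = "hamming"

    def __post_init__(self):
        self.nuft = NUFT(sample_points(self.plan).reshape(-1, 2), self.plan.grid)
        n = self.plan.grid.n_xy
        if self.coil_maps is None:
            self.coil_maps = np.ones((1, n, n), dtype=complex)
        self.coil_maps = np.asarray(self.coil_maps, dtype=complex)
        if self.coil_maps.shape[1:] != (n, n):
            raise ValueError("coil map grid does not match the plan grid")
        if self.b0_map is not None:
            self.b0_map = np.asarray(self.b0_map, dtype=float)
            if self.b0_map.shape != (n, n):
                raise ValueError("b0 map grid does not match the plan grid")
            if not np.any(self.b0_map):
                self.b0_map = None
        if self.weighting == "hamming":
            self.weights = hamming_weights(self.nuft.k, self.plan.grid.kmax)
        elif self.weighting == "none":
            self.weights = np.ones(self.nuft.n_samples)
        else:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        self.times = self.plan.times()
        self._dcf = None

    @property
    def n_coils(self) -> int:
        return self.coil_maps.shape[0]

    @property
    def n_samples(self) -> int:
        return self.nuft.n_samples

    @property
    def dcf(self) -> np.ndarray:
        """Voronoi density-compensation weights (lazy)."""
        if self._dcf is None:
            self._dcf = plan_sample_weights(self.plan)
        return self._dcf

    def _b0_phase(self, t_idx: np.ndarray) -> np.ndarray:
        """(n, n, T) phase factors exp(i 2 pi b0 t)."""
        t = self.times[t_idx]
        return np.exp(2j * math.pi * self.b0_map[:, :, None] * t[None, None, :])

    def forward(self, rho: np.ndarray, t_idx: np.ndarray | None = None) -> np.ndarray:
        """(n, n, T) image series -> (C, S, T) coil samples.

        The B0 phase is coil-independent, so all coil/time channels are
        stacked into one batched NUFT call.
        """
        n = self.plan.grid.n_xy
        rho = np.asarray(rho, dtype=complex).reshape(n, n, -1)
        T = rho.shape[-1]
        if t_idx is None:
            t_idx = np.arange(T)
        if self.b0_map is not None:
            rho = rho * self._b0_phase(t_idx)
        # (n, n, C, T) batch: coil map times the (possibly dephased) series
        x = self.coil_maps.transpose(1, 2, 0)[:, :, :, None] * rho[:, :, None, :]
        out = self.nuft.forward(x.reshape(n, n, -1))
        return out.reshape(self.n_samples, self.n_coils, T).transpose(1, 0, 2)

    def adjoint(self, samples: np.ndarray, t_idx: np.ndarray | None = None) -> np.ndarray:
        """(C, S, T) samples -> (n, n, T) coil-combined image series."""
        n = self.plan.grid.n_xy
        s = np.asarray(samples, dtype=complex).reshape(self.n_coils, self.n_samples, -1)
        T = s.shape[-1]
        if t_idx is None:
            t_idx = np.arange(T)
        imgs = self.nuft.adjoint(s.transpose(1, 0, 2).reshape(self.n_samples, -1))
        imgs = imgs.reshape(n, n, self.n_coils, T)
        out = np.einsum("cij,ijct->ijt", self.coil_maps.conj(), imgs)
        if self.b0_map is not None:
            out *= self._b0_phase(t_idx).conj()
        return out

    def forward_weighted(self, rho: np.ndarray) -> np.ndarray:
        """W F C B rho — used by the adjoint consistency test."""
        return self.forward(rho) * self.weights[None, :, None]

    def adjoint_weighted(self, samples: np.ndarray) -> np.ndarray:
        return self.adjoint(np.asarray(samples) * self.weights[None, :, None])

    def adjoint_dcf(self, samples: np.ndarray) -> np.ndarray:
        """Density-compensated, B0-conjugate adjoint (gridding) image series."""
        return self.adjoint(np.asarray(samples) * self.dcf[None, :, None])
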