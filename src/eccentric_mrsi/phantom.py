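"""Digital structural-metabolic phantoms and the coil-wise forward encoder.

`build_derenzo` rasterizes a Derenzo-style resolution phantom: five angular
sectors, each holding six tubes of one diameter (2-10 mm) in a triangular
arrangement with centre spacing twice the diameter, inside a cylindrical
NaCl bath.  Tubes carry creatine; the bath carries water only.  The
T1-shortening contrast agent of the physical phantom is folded into a
relative water-amplitude map rather than simulated.

`forward_encode` produces complex (coil, sample, time) data for any
trajectory plan by composing the voxel FIDs with coil sensitivities, the
B0 phase evolution and the exact non-uniform Fourier transform, plus
i.i.d. complex Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .operators import EncodingOperator
from .trajectories import GridSpec, TrajectoryPlan, design_comparators

__all__ = [
    "PhantomScene",
    "SpectralBasis",
    "SpectroKData",
    "default_basis",
    "build_derenzo",
    "build_brain_like",
    "make_coil_maps",
    "polynomial_b0_map",
    "synthesize_fid",
    "forward_encode",
    "make_water_reference",
]

#: Hz per ppm for 1H at 7 T (297.2 MHz)
HZ_PER_PPM_7T = 297.2
WATER_PPM = 4.7


@dataclass
class SpectralBasis:
    """Sparse prior spectral model: per metabolite a list of resonances.

    Each entry maps a metabolite name to a list of ``(ppm, amplitude)``
    pairs (optionally ``(ppm, amplitude, t2star)`` to give a resonance its
    own extra Lorentzian damping, e.g. broad lipids).  The chemical-shift
    axis is referenced so that water (4.7 ppm) sits at 0 Hz offset.
    """

    resonances: dict[str, list[tuple]]
    hz_per_ppm: float = HZ_PER_PPM_7T
    reference_ppm: float = WATER_PPM

    def __post_init__(self):
        for name, lines in self.resonances.items():
            for line in lines:
                ppm, amp = line[0], line[1]
                if amp <= 0:
                    raise ValueError(f"{name}: amplitudes must be positive")
                if not 0.0 <= ppm <= 9.0:
                    raise ValueError(f"{name}: chemical shift {ppm} ppm out of range")

    @property
    def names(self) -> list[str]:
        return list(self.resonances)

    def freq_hz(self, ppm: float) -> float:
        """Offset frequency of a resonance relative to the water carrier."""
        return (ppm - self.reference_ppm) * self.hz_per_ppm

    def fid(self, name: str, times: np.ndarray, t2star: float,
            freq_offset: float = 0.0) -> np.ndarray:
        """Unit-concentration FID of one metabolite (Lorentzian lines)."""
        if t2star <= 0:
            raise ValueError("t2star must be positive")
        t = np.asarray(times, dtype=float)
        out = np.zeros(t.shape, dtype=complex)
        for line in self.resonances[name]:
            ppm, amp = line[0], line[1]
            rate = 1.0 / t2star + (1.0 / line[2] if len(line) > 2 else 0.0)
            f = self.freq_hz(ppm) + freq_offset
            out += amp * np.exp((2j * math.pi * f - rate) * t)
        return out


def default_basis() -> SpectralBasis:
    """Compact synthetic basis: water, NAA, total creatine, choline, lipid.

    Line amplitudes are proton counts, so equal concentrations produce
    physically proportioned signals: water 2H, the NAA acetyl singlet 3H,
    creatine CH3/CH2 3H/2H, the choline trimethyl singlet 9H (which is why
    choline is a high-SNR metabolite in vivo despite its low concentration).
    The 1.3 ppm lipid line is broadened by an extra 10 ms damping.
    """
    return SpectralBasis({
        "water": [(4.7, 2.0)],
        "naa": [(2.01, 3.0)],
        "cr": [(3.03, 3.0), (3.91, 2.0)],
        "cho": [(3.2, 9.0)],
        "lipid": [(1.3, 2.0, 0.010)],
    })


@dataclass
class PhantomScene:
    """Ground-truth fields on the image grid."""

    grid: GridSpec
    tissue_masks: np.ndarray  # int labels: 0 outside, 1 bath, >=2 structures
    concentration_maps: dict[str, np.ndarray]  # mM, per metabolite
    t2star_map: np.ndarray  # s
    b0_map: np.ndarray  # Hz
    coil_maps: np.ndarray  # (C, n, n) complex
    water_amp_map: np.ndarray  # relative water amplitude
    lipid_mask: np.ndarray | None = None
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, cmap in self.concentration_maps.items():
            if np.any(cmap < 0):
                raise ValueError(f"negative concentrations in {name!r} map")

    @property
    def object_mask(self) -> np.ndarray:
        return self.tissue_masks > 0


@dataclass
class SpectroKData:
    """Measured complex samples s indexed (coil, sample j, time tau)."""

    values: np.ndarray
    plan: TrajectoryPlan
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        C, S, T = self.values.shape
        if S != self.plan.n_samples:
            raise ValueError("sample axis inconsistent with the plan")
        if not np.all(np.isfinite(self.values.view(float))):
            raise ValueError("non-finite values in k-space data")

    def subsample(self, af: float, seed: int = 0) -> "SpectroKData":
        """Retrospective undersampling: keep a circle subset (see
        :func:`~eccentric_mrsi.trajectories.subsample_plan`) and slice the
        corresponding acquired samples."""
        from .trajectories import subsample_plan

        new_plan, keep = subsample_plan(self.plan, af, seed)
        C, S, T = self.values.shape
        m = self.plan.samples_per_rev
        vals = self.values.reshape(C, self.plan.n_circles, m, T)[:, keep]
        return SpectroKData(values=vals.reshape(C, -1, T), plan=new_plan,
                            noise_sigma=self.noise_sigma, seed=self.seed)


def make_coil_maps(grid: GridSpec, n_coils: int = 8,
                   width_frac: float = 0.6) -> np.ndarray:
    """Virtual receive coils: Gaussian-weighted magnitudes centred on the FoV
    perimeter with smoothly varying phase, shape (C, n, n), complex."""
    n, fov = grid.n_xy, grid.fov_xy
    r = grid.image_coords()
    X, Y = np.meshgrid(r, r, indexing="ij")
    sigma = width_frac * fov / 2.0
    maps = np.empty((n_coils, n, n), dtype=complex)
    for c in range(n_coils):
        ang = 2.0 * math.pi * c / n_coils
        cx, cy = 0.55 * fov * math.cos(ang) / 2, 0.55 * fov * math.sin(ang) / 2
        mag = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sigma**2))
        phase = 0.7 * math.cos(ang) * X / fov + 0.7 * math.sin(ang) * Y / fov
        phase = 2 * math.pi * (phase + 0.1 * (X**2 - Y**2) / fov**2) + ang / 3.0
        maps[c] = mag * np.exp(1j * phase)
    return maps


def polynomial_b0_map(grid: GridSpec, peak_hz: float = 30.0,
                      coeffs: tuple = (0.3, -0.2, 1.0, 0.6, -0.8)) -> np.ndarray:
    """Second-order polynomial field map scaled to the requested peak |offset|."""
    r = grid.image_coords() / (grid.fov_xy / 2.0)
    X, Y = np.meshgrid(r, r, indexing="ij")
    a, b, c, d, e = coeffs
    raw = a * X + b * Y + c * X**2 + d * Y**2 + e * X * Y
    m = np.max(np.abs(raw))
    return peak_hz * raw / m if m > 0 else raw


def _triangular_offsets(n_tubes: int, spacing: float) -> list[tuple[float, float]]:
    """Centre offsets (radial, lateral) of a triangular tube packing: rows of
    1, 2, 3, ... tubes, rows spacing*sqrt(3)/2 apart, tubes spacing apart."""
    offsets = []
    row = 0
    while len(offsets) < n_tubes:
        row += 1
        radial = (row - 1) * spacing * math.sqrt(3) / 2.0
        for j in range(row):
            if len(offsets) >= n_tubes:
                break
            lateral = (j - (row - 1) / 2.0) * spacing
            offsets.append((radial, lateral))
    return offsets


def build_derenzo(
    grid: GridSpec,
    tube_diameters_mm: tuple = (2.0, 4.0, 6.0, 8.0, 10.0),
    tubes_per_set: int = 6,
    container_diameter_mm: float = 133.3,
    creatine_mM: float = 10.0,
    n_coils: int = 8,
    base_radius_mm: float = 14.0,
    bath_water_amp: float = 0.35,
    tube_water_amp: float = 1.0,
    t2star_s: float = 0.05,
    b0_peak_hz: float = 0.0,
) -> PhantomScene:
    """Derenzo-style resolution phantom on the given grid.

    One angular sector per diameter; in each sector ``tubes_per_set`` tubes
    of that diameter at centre spacing 2 x diameter in triangular
    configuration, the first row ``base_radius_mm`` from the centre.  Tubes
    carry creatine at ``creatine_mM``; the bath carries water only.  The
    contrast-agent T1 shortening of the tubes enters as a higher relative
    water amplitude (``tube_water_amp`` vs ``bath_water_amp``).
    """
    n = grid.n_xy
    r = grid.image_coords() * 1e3  # mm
    X, Y = np.meshgrid(r, r, indexing="ij")
    R_cont = container_diameter_mm / 2.0
    labels = np.zeros((n, n), dtype=int)
    labels[X**2 + Y**2 <= R_cont**2] = 1
    label_names = {1: "bath"}
    cr_map = np.zeros((n, n))
    n_sets = len(tube_diameters_mm)
    for s, d in enumerate(tube_diameters_mm):
        sector_ang = math.pi / 2.0 + 2.0 * math.pi * s / max(n_sets, 1)
        ca, sa = math.cos(sector_ang), math.sin(sector_ang)
        for (radial, lateral) in _triangular_offsets(tubes_per_set, 2.0 * d):
            rad = base_radius_mm + radial
            cx = rad * ca - lateral * sa
            cy = rad * sa + lateral * ca
            if math.hypot(cx, cy) + d / 2.0 > R_cont:
                raise ValueError(
                    f"tube set with diameter {d} mm does not fit inside the "
                    f"{container_diameter_mm} mm container"
                )
            tube = (X - cx) ** 2 + (Y - cy) ** 2 <= (d / 2.0) ** 2
            if not tube.any():
                # tube smaller than a voxel: keep at least its centre voxel
                ci = np.unravel_index(np.argmin((X - cx) ** 2 + (Y - cy) ** 2),
                                      X.shape)
                tube[ci] = True
            labels[tube] = 2 + s
            cr_map[tube] = creatine_mM
        label_names[2 + s] = f"tubes_{d:g}mm"
    water_amp = np.where(labels >= 2, tube_water_amp,
                         np.where(labels == 1, bath_water_amp, 0.0))
    scene = PhantomScene(
        grid=grid,
        tissue_masks=labels,
        concentration_maps={"cr": cr_map},
        t2star_map=np.full((n, n), t2star_s),
        b0_map=polynomial_b0_map(grid, b0_peak_hz) * (labels > 0),
        coil_maps=make_coil_maps(grid, n_coils),
        water_amp_map=water_amp,
        label_names=label_names,
    )
    return scene


def build_brain_like(
    grid: GridSpec,
    n_coils: int = 8,
    b0_peak_hz: float = 30.0,
    t2star_s: float = 0.04,
    lipid_amp: float = 50.0,
) -> PhantomScene:
    """Brain-like disc with NAA/Cr/Cho maps, a skull-lipid annulus and a
    second-order B0 map — the standard scene for recovery tests.

    The brain disc splits into a white-matter-like interior ellipse and a
    gray-matter-like shell, with typical in vivo contrasts (mM): NAA 12 GM /
    9 WM, total creatine 9.6 GM / 6.4 WM, choline 2.0 GM / 2.8 WM plus a
    focal lesion-like choline hotspot, so each map carries distinct,
    realistic spatial structure.
    """
    n = grid.n_xy
    r = grid.image_coords() / (grid.fov_xy / 2.0)
    X, Y = np.meshgrid(r, r, indexing="ij")
    rr = np.hypot(X, Y)
    brain = rr <= 0.72
    annulus = (rr > 0.78) & (rr <= 0.92)
    wm = brain & ((X / 0.45) ** 2 + (Y / 0.32) ** 2 <= 1.0)
    gm = brain & ~wm
    lesion = ((X - 0.35) ** 2 + (Y + 0.28) ** 2) < 0.03
    labels = np.zeros((n, n), dtype=int)
    labels[annulus] = 1
    labels[brain] = 2
    naa = 12.0 * gm + 9.0 * wm
    cr = 9.6 * gm + 6.4 * wm
    cho = 2.0 * gm + 2.8 * wm + 2.5 * (lesion & brain)
    lipid = lipid_amp * annulus.astype(float)
    water_amp = 1.0 * brain + 0.9 * annulus
    return PhantomScene(
        grid=grid,
        tissue_masks=labels,
        concentration_maps={"naa": naa, "cr": cr, "cho": cho, "lipid": lipid},
        t2star_map=np.full((n, n), t2star_s),
        b0_map=polynomial_b0_map(grid, b0_peak_hz) * (labels > 0),
        coil_maps=make_coil_maps(grid, n_coils),
        water_amp_map=water_amp,
        lipid_mask=annulus,
        label_names={1: "lipid_annulus", 2: "brain"},
    )


def synthesize_fid(
    basis: SpectralBasis,
    concentrations: dict[str, float],
    t2star: float,
    times: np.ndarray,
    freq_offset: float = 0.0,
) -> np.ndarray:
    """Voxel FID  s(t) = sum_m c_m sum_j a_mj exp(i2pi(f_mj+off)t - t/T2*).

    Pure complex-exponential (Lorentzian-line) model; linear in the
    concentrations.
    """
    if t2star <= 0:
        raise ValueError("t2star must be positive")
    t = np.asarray(times, dtype=float)
    out = np.zeros(t.shape, dtype=complex)
    for name, c in concentrations.items():
        if c == 0:
            continue
        out += c * basis.fid(name, t, t2star, freq_offset)
    return out


def scene_image_series(scene: PhantomScene, basis: SpectralBasis,
                       times: np.ndarray, water_scale: float = 0.0) -> np.ndarray:
    """Ground-truth rho(r, t) of a scene, shape (n, n, T).

    Metabolite FIDs scale with the concentration maps; water contributes
    ``water_scale * water_amp_map`` at the carrier.  B0 evolution is *not*
    included here — it belongs to the encoding operator.
    """
    n = scene.grid.n_xy
    t = np.asarray(times, dtype=float)
    rho = np.zeros((n, n, t.size), dtype=complex)
    # voxels share T2*; group by unique T2* value to vectorize
    for t2 in np.unique(scene.t2star_map[scene.object_mask]):
        vox = scene.t2star_map == t2
        for name, cmap in scene.concentration_maps.items():
            if name not in basis.resonances or not np.any(cmap[vox]):
                continue
            fid = basis.fid(name, t, float(t2))
            rho[vox] += cmap[vox][:, None] * fid[None, :]
        if water_scale != 0.0:
            wfid = basis.fid("water", t, float(t2))
            rho[vox] += water_scale * scene.water_amp_map[vox][:, None] * wfid[None, :]
    return rho


def forward_encode(
    scene: PhantomScene,
    basis: SpectralBasis,
    plan: TrajectoryPlan,
    noise_sigma: float = 0.0,
    seed: int | None = 0,
    water_scale: float = 0.0,
    n_time: int | None = None,
) -> SpectroKData:
    """Simulate the acquisition of a scene with a plan.

    s_{c,j,tau} = sum_i C_c(r_i) e^{i2pi b0(r_i) t_tau} e^{i2pi k_j . r_i}
    rho(r_i, t_tau) + eps,  with eps i.i.d. complex Gaussian of standard
    deviation ``noise_sigma`` (per complex sample), independent across coils.
    """
    if scene.grid != plan.grid:
        raise ValueError("scene grid does not match plan grid")
    T = plan.n_time if n_time is None else n_time
    times = np.arange(T) / plan.sbw
    rho = scene_image_series(scene, basis, times, water_scale=water_scale)
    op = EncodingOperator(plan, coil_maps=scene.coil_maps, b0_map=scene.b0_map,
                          weighting="none")
    values = op.forward(rho, t_idx=np.arange(T))
    if noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        noise = rng.standard_normal(values.shape) + 1j * rng.standard_normal(values.shape)
        values = values + (noise_sigma / math.sqrt(2.0)) * noise
    return SpectroKData(values=values, plan=plan, noise_sigma=noise_sigma, seed=seed)


def make_water_reference(
    scene: PhantomScene,
    plan_lowres: TrajectoryPlan | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = 1,
    n_time: int = 32,
) -> SpectroKData:
    """Rapid water-reference acquisition (water suppression off).

    Defaults to a fully sampled low-resolution rosette plan (24x24 in-plane
    over the scene FoV).  Only the water resonance contributes, at 0 Hz
    offset plus the scene's B0 phase; used downstream for coil-sensitivity
    and B0-map estimation and as the quantification reference.
    """
    if plan_lowres is None:
        lowgrid = GridSpec(n_xy=24, fov_xy=scene.grid.fov_xy)
        plan_lowres = design_comparators(lowgrid, "rosette", af=1.0, seed=0,
                                         sbw=2280.0, n_time=n_time)
    T = min(n_time, plan_lowres.n_time)
    times = np.arange(T) / plan_lowres.sbw
    n = scene.grid.n_xy
    # water-only image series on the acquisition grid (encoded with the
    # low-res plan's NUFT, which only needs k coordinates)
    t2 = scene.t2star_map
    rho = scene.water_amp_map[:, :, None] * np.exp(-times[None, None, :] / t2[:, :, None])
    op = EncodingOperator(plan_lowres, coil_maps=None, b0_map=None, weighting="none")
    if plan_lowres.grid.n_xy != n:
        # encode the full-resolution scene with the low-res plan's samples:
        # build a NUFT on the scene grid at the plan's k locations
        from .operators import NUFT
        from .trajectories import sample_points as _sp

        nuft = NUFT(_sp(plan_lowres).reshape(-1, 2), scene.grid)
        vals = np.empty((scene.coil_maps.shape[0], nuft.n_samples, T), dtype=complex)
        phase = (np.exp(2j * math.pi * scene.b0_map[:, :, None] * times[None, None, :])
                 if np.any(scene.b0_map) else None)
        for c in range(scene.coil_maps.shape[0]):
            x = scene.coil_maps[c][:, :, None] * rho
            if phase is not None:
                x = x * phase
            vals[c] = nuft.forward(x)
    else:
        op = EncodingOperator(plan_lowres, coil_maps=scene.coil_maps,
                              b0_map=scene.b0_map, weighting="none")
        vals = op.forward(rho, t_idx=np.arange(T))
    if noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        noise = rng.standard_normal(vals.shape) + 1j * rng.standard_normal(vals.shape)
        vals = vals + (noise_sigma / math.sqrt(2.0)) * noise
    plan_T = TrajectoryPlan(grid=plan_lowres.grid, circles=plan_lowres.circles,
                            samples_per_rev=plan_lowres.samples_per_rev,
                            sbw=plan_lowres.sbw, n_time=T,
                            family=plan_lowres.family, af=plan_lowres.af,
                            seed=plan_lowres.seed)
    return SpectroKData(values=vals, plan=plan_T, noise_sigma=noise_sigma, seed=seed)
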