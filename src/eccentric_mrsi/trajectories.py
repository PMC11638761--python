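"""Design of circular k-space sampling plans for spatial-spectral MRSI.

Eccentric-circle encoding places small circles of radius ``R`` at random
polar positions ``(r_c, phi_c)`` in the kx-ky plane, subject to a minimal
Nyquist spacing between consecutive circle centres, plus a small rosette-like
subset through the k-space origin.  Because every circle is traversed once
per spectral dwell, the circle radius — not the full extent of k-space —
sets the gradient amplitude and slew-rate demand, which is what allows high
matrix sizes and spectral bandwidths without temporal interleaving.

Comparator families (rosette, concentric rings, uniformly distributed
circles), per-sample Voronoi density compensation, gradient/slew arithmetic
and sequence timing live here as well.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi, QhullError
from shapely.geometry import Point, Polygon

__all__ = [
    "GridSpec",
    "CircleSpec",
    "TrajectoryPlan",
    "GradientDemand",
    "SequenceTiming",
    "PlacementError",
    "full_sampling_count",
    "rosette_count",
    "design_eccentric_plane",
    "design_stack",
    "design_comparators",
    "subsample_plan",
    "sample_points",
    "gradient_demand",
    "max_sbw",
    "timing",
    "sequence_timing",
    "voronoi_density",
]

#: gyromagnetic ratio of 1H over 2*pi, in Hz/T
GAMMA_BAR_1H = 42.577e6


class PlacementError(RuntimeError):
    """Raised when a circle centre satisfying the overlap rule cannot be drawn."""


@dataclass(frozen=True)
class GridSpec:
    """Cartesian image/k-space grid of the acquisition.

    Parameters
    ----------
    n_xy : int
        In-plane matrix size (even, >= 4).
    fov_xy : float
        In-plane field of view in metres.
    n_z : int
        Number of kz partitions (1 for a purely 2D plan).
    fov_z : float or None
        Slab field of view in metres (required when ``n_z > 1``).
    """

    n_xy: int
    fov_xy: float
    n_z: int = 1
    fov_z: float | None = None

    def __post_init__(self):
        if self.n_xy < 4 or self.n_xy % 2:
            raise ValueError(f"n_xy must be even and >= 4, got {self.n_xy}")
        if self.fov_xy <= 0:
            raise ValueError("fov_xy must be positive")
        if self.n_z > 1 and (self.fov_z is None or self.fov_z <= 0):
            raise ValueError("fov_z must be positive when n_z > 1")

    @property
    def dk(self) -> float:
        """Nyquist spacing 1/FoV in cycles/m."""
        return 1.0 / self.fov_xy

    @property
    def kmax(self) -> float:
        """Largest in-plane k-space coordinate n/(2 FoV) in cycles/m."""
        return self.n_xy / (2.0 * self.fov_xy)

    @property
    def dkz(self) -> float:
        if self.n_z == 1:
            return 0.0
        return 1.0 / self.fov_z

    def image_coords(self) -> np.ndarray:
        """Centred in-plane grid coordinates r_i = (i - n/2) * FoV / n, in m."""
        i = np.arange(self.n_xy)
        return (i - self.n_xy / 2.0) * self.fov_xy / self.n_xy


@dataclass(frozen=True)
class CircleSpec:
    """One circular readout: centre (r_c, phi_c), radius R, start phase theta0."""

    r_c: float
    phi_c: float
    R: float
    theta0: float = 0.0
    kz_index: int = 0

    def __post_init__(self):
        if self.R <= 0:
            raise ValueError("circle radius R must be positive")
        if self.r_c < 0:
            raise ValueError("centre radius r_c must be non-negative")

    @property
    def center(self) -> tuple[float, float]:
        return (self.r_c * math.cos(self.phi_c), self.r_c * math.sin(self.phi_c))


@dataclass
class TrajectoryPlan:
    """A full sampling plan: ordered circles plus acquisition metadata."""

    grid: GridSpec
    circles: list[CircleSpec]
    samples_per_rev: int
    sbw: float
    n_time: int
    family: str
    af: float
    seed: int | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.samples_per_rev < 4:
            raise ValueError("samples_per_rev must be >= 4")
        tol = self.grid.kmax + self.grid.dk / 2 + 1e-9
        for c in self.circles:
            if c.r_c + c.R > tol:
                raise ValueError(
                    f"circle at r_c={c.r_c:g} with R={c.R:g} exceeds kmax + dk/2"
                )

    @property
    def n_circles(self) -> int:
        return len(self.circles)

    @property
    def n_samples(self) -> int:
        """Total k-space samples per spectral time point."""
        return len(self.circles) * self.samples_per_rev

    def times(self) -> np.ndarray:
        """Spectral time stamps t_tau = tau / sbw (one per revolution)."""
        return np.arange(self.n_time) / self.sbw


@dataclass(frozen=True)
class GradientDemand:
    """Constant gradient amplitude/slew needed to traverse a circle."""

    amplitude: float  # mT/m
    slew: float  # T/m/s
    gamma_bar: float = GAMMA_BAR_1H

    def __post_init__(self):
        if self.amplitude < 0 or self.slew < 0:
            raise ValueError("gradient demand must be non-negative")


@dataclass(frozen=True)
class SequenceTiming:
    tr: float
    n_excitations: int
    ta: float
    fid_duration: float


def _default_samples_per_rev(R: float, fov_xy: float) -> int:
    """Nyquist count along the circumference, ceil(2 pi R FoV)."""
    return max(4, math.ceil(2.0 * math.pi * R * fov_xy))


def full_sampling_count(n: int, kmax: float, R: float) -> int:
    """Circles needed to fully sample one partition: ceil(pi n kmax / (2 R)).

    For ``R = kmax/2`` and ``n = 64`` this gives the 202 circles of the
    fully sampled eccentric/uniform comparison; for ``R = kmax`` it collapses
    to the rosette count ceil(pi n / 2).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if R <= 0 or kmax <= 0:
        raise ValueError("R and kmax must be positive")
    if R > kmax:
        raise ValueError("R cannot exceed kmax")
    return math.ceil(math.pi * n * kmax / (2.0 * R))


def rosette_count(n: int) -> int:
    """Circles of a fully sampled rosette trajectory: ceil(pi n / 2)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return math.ceil(math.pi * n / 2.0)


def _capped_rosette_subset(count: int, rosette_fraction: float, R: float, dk: float) -> int:
    """Number of origin-crossing rosette circles, capped so that consecutive
    rosette centres (on the radius-R circle) stay >= dk apart."""
    n_ros = math.ceil(rosette_fraction * count)
    if n_ros <= 1:
        return n_ros
    if 2.0 * R <= dk:
        return 1
    # consecutive centres are 2 R sin(pi / n_ros) apart
    n_cap = int(math.pi / math.asin(min(1.0, dk / (2.0 * R))))
    return max(1, min(n_ros, n_cap))


def design_eccentric_plane(
    grid: GridSpec,
    R: float,
    af: float = 1.0,
    rosette_fraction: float = 0.04,
    seed: int | None = 0,
    kz_index: int = 0,
    *,
    kmax: float | None = None,
    n_eff: int | None = None,
    rng: np.random.Generator | None = None,
    max_draws: int = 1000,
) -> list[CircleSpec]:
    """Draw one eccentric-circle encoding plane.

    The first ``ceil(rosette_fraction * count)`` circles are placed rosette
    fashion through the k-space origin (r_c = R, uniformly spaced azimuths);
    the remaining centres are drawn with uniform polar coordinates
    r_c ~ U[0, max(kmax - R, R)], phi_c ~ U[0, 2 pi), re-drawn until the
    distance to the previously accepted centre is at least the Nyquist
    distance dk = 1/FoV.

    ``kmax``/``n_eff`` override the grid values for reduced-extent partitions
    of an ellipsoid stack.  Deterministic given ``seed`` (or ``rng``).
    """
    if af < 1:
        raise ValueError("acceleration factor af must be >= 1")
    if not 0 <= rosette_fraction <= 0.05:
        raise ValueError("rosette_fraction must be within [0, 0.05]")
    kmax_eff = grid.kmax if kmax is None else kmax
    n = grid.n_xy if n_eff is None else n_eff
    if R <= 0 or R > kmax_eff:
        raise ValueError("R must satisfy 0 < R <= kmax of the partition")
    dk = grid.dk
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed))

    full = full_sampling_count(n, kmax_eff, R)
    count = max(1, round(full / af))
    n_ros = _capped_rosette_subset(count, rosette_fraction, R, dk)

    circles: list[CircleSpec] = []
    for i in range(n_ros):
        phi = 2.0 * math.pi * i / n_ros
        circles.append(
            CircleSpec(r_c=R, phi_c=phi, R=R,
                       theta0=rng.uniform(0.0, 2.0 * math.pi), kz_index=kz_index)
        )

    r_max = max(kmax_eff - R, R)
    prev = circles[-1].center if circles else None
    for i in range(n_ros, count):
        placed = False
        for _ in range(max_draws):
            r_c = rng.uniform(0.0, r_max)
            phi_c = rng.uniform(0.0, 2.0 * math.pi)
            x, y = r_c * math.cos(phi_c), r_c * math.sin(phi_c)
            if prev is None or math.hypot(x - prev[0], y - prev[1]) >= dk:
                circles.append(
                    CircleSpec(r_c=r_c, phi_c=phi_c, R=R,
                               theta0=rng.uniform(0.0, 2.0 * math.pi),
                               kz_index=kz_index)
                )
                prev = (x, y)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place circle {i} after {max_draws} draws "
                f"under the Nyquist overlap rule"
            )
    return circles


def _partition_kz_indices(n_z: int) -> np.ndarray:
    """kz partition indices centred on zero (even n_z drops the +n_z/2 edge)."""
    return np.arange(n_z) - n_z // 2


def design_stack(
    grid: GridSpec,
    R: float,
    af: float = 1.0,
    rosette_fraction: float = 0.04,
    seed: int = 0,
    coverage: str = "ellipsoid",
    sbw: float = 2280.0,
    n_time: int = 500,
) -> TrajectoryPlan:
    """Stack-of-eccentric 3D plan with ellipsoid (default) or cylinder coverage.

    For ellipsoid coverage the per-partition in-plane extent is
    ``kmax(kz) = kmax * sqrt(1 - (kz/kz_max)^2)`` with
    ``kz_max = (n_z/2 + 1) dk_z`` so every partition keeps a positive extent;
    the effective matrix size entering the circle-count formula is
    ``n(kz) = round(2 FoV kmax(kz))``.  Each partition draws its circles from
    an independent substream of the master seed, so partition plans do not
    depend on the order in which they are generated.
    """
    if coverage not in ("ellipsoid", "cylinder"):
        raise ValueError(f"unknown coverage {coverage!r}")
    kz_idx = _partition_kz_indices(grid.n_z)
    kz_max_idx = grid.n_z / 2.0 + 1.0
    circles: list[CircleSpec] = []
    warn_list: list[str] = []
    for i in kz_idx:
        if coverage == "ellipsoid" and grid.n_z > 1:
            frac = math.sqrt(max(0.0, 1.0 - (i / kz_max_idx) ** 2))
        else:
            frac = 1.0
        kmax_i = grid.kmax * frac
        n_i = max(2, round(2.0 * grid.fov_xy * kmax_i))
        R_i = R
        if R_i > kmax_i:
            R_i = kmax_i
            warn_list.append(
                f"partition kz={i}: circle radius clamped to kmax(kz)={kmax_i:g}"
            )
        ss = np.random.SeedSequence(seed, spawn_key=(int(i) + 2**20,))
        circles.extend(
            design_eccentric_plane(
                grid, R_i, af, rosette_fraction,
                kz_index=int(i), kmax=kmax_i, n_eff=n_i,
                rng=np.random.default_rng(ss),
            )
        )
    m = _default_samples_per_rev(R, grid.fov_xy)
    return TrajectoryPlan(
        grid=grid, circles=circles, samples_per_rev=m, sbw=sbw, n_time=n_time,
        family="eccentric", af=af, seed=seed, warnings=warn_list,
    )


def design_comparators(
    grid: GridSpec,
    family: str,
    af: float = 1.0,
    seed: int = 0,
    *,
    R: float | None = None,
    sbw: float = 2280.0,
    n_time: int = 500,
) -> TrajectoryPlan:
    """Comparator circular trajectories: rosette, concentric rings or
    uniformly distributed circles (single partition).

    rosette
        ceil(rosette_count(n)/af) circles of radius kmax/2 centred at
        distance kmax/2 from the origin with uniformly spaced azimuths.
    concentric
        rings of radius i*dk, i = 1 ... n/2 - 1, thinned by taking every
        af-th ring.
    uniform
        the eccentric count rule, but centres spread uniformly (in area)
        over the disc of radius kmax - R, i.e. no density shaping.
    """
    if af < 1:
        raise ValueError("acceleration factor af must be >= 1")
    n, kmax, dk = grid.n_xy, grid.kmax, grid.dk
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    circles: list[CircleSpec] = []
    if family == "rosette":
        Rr = kmax / 2.0
        count = math.ceil(rosette_count(n) / af)
        for i in range(count):
            circles.append(
                CircleSpec(r_c=Rr, phi_c=2.0 * math.pi * i / count, R=Rr,
                           theta0=rng.uniform(0, 2 * math.pi))
            )
        m = _default_samples_per_rev(Rr, grid.fov_xy)
    elif family == "concentric":
        radii = dk * np.arange(1, n // 2)
        step = max(1, int(round(af)))
        radii = radii[::step]
        for r in radii:
            circles.append(CircleSpec(r_c=0.0, phi_c=0.0, R=float(r),
                                      theta0=rng.uniform(0, 2 * math.pi)))
        m = _default_samples_per_rev(float(dk * (n // 2 - 1)), grid.fov_xy)
    elif family == "uniform":
        Ru = kmax / 2.0 if R is None else R
        count = max(1, round(full_sampling_count(n, kmax, Ru) / af))
        r_disc = max(kmax - Ru, Ru)
        for _ in range(count):
            r_c = r_disc * math.sqrt(rng.uniform())
            circles.append(
                CircleSpec(r_c=r_c, phi_c=rng.uniform(0, 2 * math.pi), R=Ru,
                           theta0=rng.uniform(0, 2 * math.pi))
            )
        m = _default_samples_per_rev(Ru, grid.fov_xy)
    else:
        raise ValueError(f"unknown trajectory family {family!r}")
    return TrajectoryPlan(grid=grid, circles=circles, samples_per_rev=m,
                          sbw=sbw, n_time=n_time, family=family, af=af, seed=seed)


def design_eccentric_2d(
    grid: GridSpec,
    R: float,
    af: float = 1.0,
    rosette_fraction: float = 0.04,
    seed: int = 0,
    sbw: float = 2280.0,
    n_time: int = 500,
) -> TrajectoryPlan:
    """Single-partition eccentric plan wrapped in a :class:`TrajectoryPlan`."""
    circles = design_eccentric_plane(grid, R, af, rosette_fraction, seed)
    m = _default_samples_per_rev(R, grid.fov_xy)
    return TrajectoryPlan(grid=grid, circles=circles, samples_per_rev=m,
                          sbw=sbw, n_time=n_time, family="eccentric",
                          af=af, seed=seed)


def subsample_plan(plan: TrajectoryPlan, af: float, seed: int = 0) -> TrajectoryPlan:
    """Retrospective undersampling: keep round(Nc/af) circles of an acquired plan.

    The origin-crossing rosette subset (circles with r_c == R) is always
    retained — it exists precisely to guarantee central k-space coverage —
    and the remainder is a seeded random subset, mirroring how an
    acquisition designed at the higher acceleration would be laid out.
    Returns the new plan and the indices of the kept circles (for slicing
    already-acquired data); circle order is preserved.
    """
    if af < 1:
        raise ValueError("af must be >= 1")
    n_keep = max(1, round(plan.n_circles / af))
    is_central = np.array([abs(c.r_c - c.R) < 1e-12 for c in plan.circles])
    central = np.flatnonzero(is_central)
    rest = np.flatnonzero(~is_central)
    if len(central) >= n_keep:
        keep = central[:n_keep]
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        extra = rng.choice(rest, size=n_keep - len(central), replace=False)
        keep = np.sort(np.concatenate([central, extra]))
    circles = [plan.circles[i] for i in keep]
    new_plan = TrajectoryPlan(grid=plan.grid, circles=circles,
                              samples_per_rev=plan.samples_per_rev, sbw=plan.sbw,
                              n_time=plan.n_time, family=plan.family,
                              af=plan.af * af, seed=plan.seed,
                              warnings=list(plan.warnings))
    return new_plan, keep


def sample_points(plan: TrajectoryPlan) -> np.ndarray:
    """k-space sample coordinates, shape (n_circles, m, 2), in cycles/m.

    ``k_j = centre + R (cos(2 pi j/m + theta0), sin(2 pi j/m + theta0))``.
    The same m points of each circle are re-visited once per spectral dwell,
    so one spatial set serves every time index.
    """
    m = plan.samples_per_rev
    if m < 4:
        raise ValueError("samples_per_rev must be >= 4")
    ang = 2.0 * math.pi * np.arange(m) / m
    out = np.empty((plan.n_circles, m, 2))
    for i, c in enumerate(plan.circles):
        cx, cy = c.center
        out[i, :, 0] = cx + c.R * np.cos(ang + c.theta0)
        out[i, :, 1] = cy + c.R * np.sin(ang + c.theta0)
    return out


def gradient_demand(R: float, sbw: float, gamma_bar: float = GAMMA_BAR_1H) -> GradientDemand:
    """Constant gradient amplitude and slew rate for one circle per dwell.

    Traversing a circle of radius R (cycles/m) once per spectral dwell means
    an angular rate omega = 2 pi sbw, hence G = R omega / gamma_bar and
    S = G omega, both constant in time — the key hardware advantage of
    small-radius circles.
    """
    if R <= 0 or sbw <= 0:
        raise ValueError("R and sbw must be positive")
    omega = 2.0 * math.pi * sbw
    amp_T_per_m = R * omega / gamma_bar
    return GradientDemand(amplitude=amp_T_per_m * 1e3, slew=amp_T_per_m * omega,
                          gamma_bar=gamma_bar)


def max_sbw(R: float, limits: dict, gamma_bar: float = GAMMA_BAR_1H) -> float:
    """Largest spectral bandwidth before hitting gradient hardware limits.

    ``limits`` carries ``g_max`` in mT/m and ``s_max`` in T/m/s.  Inverts
    :func:`gradient_demand`:  sbw_G = g_max gamma_bar / (2 pi R) and
    sbw_S = sqrt(s_max gamma_bar / R) / (2 pi); the minimum of the two wins.
    Infinite limits yield ``inf``.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    g_max = limits.get("g_max", math.inf)
    s_max = limits.get("s_max", math.inf)
    if g_max <= 0 or s_max <= 0:
        raise ValueError("limits must be positive")
    sbw_g = (g_max * 1e-3) * gamma_bar / (2.0 * math.pi * R) if math.isfinite(g_max) else math.inf
    sbw_s = math.sqrt(s_max * gamma_bar / R) / (2.0 * math.pi) if math.isfinite(s_max) else math.inf
    return min(sbw_g, sbw_s)


def sequence_timing(n_excitations: int, tr: float, n_time: int | None = None,
                    sbw: float | None = None) -> SequenceTiming:
    """TA = n_excitations * TR; FID duration = n_time / sbw.

    ``n_excitations`` may be given explicitly (e.g. a protocol's printed
    circle count) rather than derived from a designed plan.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    fid = float(n_time) / sbw if (n_time and sbw) else float("nan")
    return SequenceTiming(tr=tr, n_excitations=n_excitations,
                          ta=n_excitations * tr, fid_duration=fid)


def timing(plan: TrajectoryPlan, tr: float) -> SequenceTiming:
    """Sequence timing of a designed plan (one excitation per circle)."""
    return sequence_timing(plan.n_circles, tr, plan.n_time, plan.sbw)


def format_ta(ta_seconds: float) -> str:
    """Human-readable acquisition time, e.g. 1119.8 s -> '18 min 40 s'."""
    minutes = int(ta_seconds // 60)
    seconds = int(round(ta_seconds - 60 * minutes))
    if seconds == 60:
        minutes, seconds = minutes + 1, 0
    return f"{minutes} min {seconds} s"


def _polygon_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def voronoi_density(points: np.ndarray, clip_radius: float | None = None,
                    n_arc: int = 4096) -> np.ndarray:
    """Per-sample Voronoi density-compensation weights.

    Each weight is the area of the sample's Voronoi cell, with cells clipped
    to the disc of radius ``clip_radius`` (default: kmax + dk/2 is what plan
    users pass; falls back to 1.02 x the largest sample radius).  Exactly
    coincident samples share their cell's area equally.  The weights sum to
    the clipped-disc area (the disc is realized as an ``n_arc``-gon).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 points")
    sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if sv[1] <= 1e-12 * max(sv[0], 1.0):
        raise ValueError("all points are collinear; Voronoi weights undefined")
    if clip_radius is None:
        clip_radius = 1.02 * float(np.max(np.hypot(pts[:, 0], pts[:, 1])))

    # merge exactly coincident points; split their area equally afterwards
    scale = max(clip_radius, 1.0)
    keyed = np.round(pts / (1e-12 * scale)).astype(np.int64)
    uniq, inverse, counts = np.unique(keyed, axis=0, return_inverse=True,
                                      return_counts=True)
    upts = np.zeros((len(uniq), 2))
    np.add.at(upts, inverse, pts)
    upts /= counts[:, None]

    if len(upts) < 4:
        raise ValueError("fewer than 4 distinct points")
    # ghost ring guarantees every real cell is finite
    n_ghost = max(64, int(4 * math.sqrt(len(upts))))
    ang = 2.0 * math.pi * np.arange(n_ghost) / n_ghost
    ghost = 3.0 * clip_radius * np.column_stack([np.cos(ang), np.sin(ang)])
    try:
        vor = Voronoi(np.vstack([upts, ghost]))
    except QhullError as e:  # pragma: no cover - degenerate geometry
        raise ValueError(f"degenerate point set for Voronoi weights: {e}") from e

    disc = Point(0.0, 0.0).buffer(clip_radius, quad_segs=n_arc // 4)
    # a cell whose vertices all lie inside the inscribed circle of the
    # disc polygon is entirely inside it -> plain shoelace area
    r_in = clip_radius * math.cos(math.pi / n_arc)
    areas = np.empty(len(upts))
    for i in range(len(upts)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            areas[i] = 0.0
            continue
        verts = vor.vertices[region]
        if np.all(np.hypot(verts[:, 0], verts[:, 1]) <= r_in):
            areas[i] = _polygon_area(verts)
        else:
            areas[i] = Polygon(verts).intersection(disc).area
    weights = areas[inverse] / counts[inverse]
    if not np.all(np.isfinite(weights)) or np.any(weights < 0):
        raise ValueError("non-finite or negative Voronoi weights")
    if np.all(weights == 0):
        raise ValueError("all Voronoi weights are zero (collinear points?)")
    return weights


def plan_sample_weights(plan: TrajectoryPlan) -> np.ndarray:
    """Voronoi weights for all samples of a (2D) plan, flattened (S,)."""
    pts = sample_points(plan).reshape(-1, 2)
    return voronoi_density(pts, clip_radius=plan.grid.kmax + plan.grid.dk / 2)


def eccentric_center_density(grid: GridSpec, R: float, n_centers: int,
                             seed: int = 0, rosette_fraction: float = 0.0,
                             points_per_circle: int = 64) -> np.ndarray:
    """Monte-Carlo k-space sample cloud from the eccentric placement rule.

    Draws ``n_centers`` circle centres (sequential Nyquist overlap rule
    applied, no rosette subset by default) and returns the sampled k-points,
    for radial sampling-density checks against the analytic 1/||k|| law.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dk, kmax = grid.dk, grid.kmax
    r_max = max(kmax - R, R)
    centers = np.empty((n_centers, 2))
    prev = None
    i = 0
    while i < n_centers:
        r_c = r_max * rng.uniform()
        phi = rng.uniform(0, 2 * math.pi)
        x, y = r_c * math.cos(phi), r_c * math.sin(phi)
        if prev is None or math.hypot(x - prev[0], y - prev[1]) >= dk:
            centers[i] = (x, y)
            prev = (x, y)
            i += 1
    ang = 2 * math.pi * np.arange(points_per_circle) / points_per_circle
    th0 = rng.uniform(0, 2 * math.pi, size=n_centers)
    pts = centers[:, None, :] + R * np.stack(
        [np.cos(ang[None, :] + th0[:, None]), np.sin(ang[None, :] + th0[:, None])],
        axis=-1,
    )
    return pts.reshape(-1, 2)


def analytic_radial_mass(R: float, r_max: float, edges: np.ndarray,
                         n_quad: int = 4000) -> np.ndarray:
    """Analytic per-annulus sampling mass of the eccentric placement model.

    For a centre at radius r (uniform on [0, r_max]) and a point uniform on
    the circle of radius R around it, P(|k| < s | r) = 1 - arccos(x)/pi with
    x = clip((s^2 - r^2 - R^2) / (2 r R), -1, 1).  Integrating over r gives
    the cumulative radial mass; differencing over ``edges`` gives annulus
    masses.  Serves as the independent oracle for the 1/||k|| density law.
    """
    r = (np.arange(n_quad) + 0.5) * (r_max / n_quad)

    def cdf(s: float) -> float:
        x = (s**2 - r**2 - R**2) / (2.0 * r * R)
        frac = 1.0 - np.arccos(np.clip(x, -1.0, 1.0)) / math.pi
        return float(np.mean(frac))

    c = np.array([cdf(s) for s in edges])
    return np.diff(c)
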