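"""HDF5 / NIfTI / CSV persistence for plans, k-space data and maps."""

from __future__ import annotations

import csv

import h5py
import nibabel as nib
import numpy as np

from .phantom import SpectroKData
from .trajectories import CircleSpec, GridSpec, TrajectoryPlan, sample_points

__all__ = [
    "save_plan",
    "load_plan",
    "dump_circles_csv",
    "save_kdata",
    "load_kdata",
    "save_map_nifti",
]

_CIRCLE_COLUMNS = ("kz_index", "r_c", "phi_c", "R", "theta0")


def _circle_table(plan: TrajectoryPlan) -> np.ndarray:
    return np.array([(c.kz_index, c.r_c, c.phi_c, c.R, c.theta0)
                     for c in plan.circles])


def save_plan(plan: TrajectoryPlan, path) -> None:
    """Write a plan: /circles table, /k_samples array and /meta attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("circles", data=_circle_table(plan))
        f["circles"].attrs["columns"] = ",".join(_CIRCLE_COLUMNS)
        f.create_dataset("k_samples", data=sample_points(plan))
        meta = f.create_group("meta")
        meta.attrs.update({
            "n_xy": plan.grid.n_xy, "n_z": plan.grid.n_z,
            "fov_xy": plan.grid.fov_xy, "fov_z": plan.grid.fov_z or 0.0,
            "samples_per_rev": plan.samples_per_rev, "sbw": plan.sbw,
            "n_time": plan.n_time, "family": plan.family, "af": plan.af,
            "seed": -1 if plan.seed is None else plan.seed,
            "warnings": "\n".join(plan.warnings),
        })


def load_plan(path) -> TrajectoryPlan:
    with h5py.File(path, "r") as f:
        tab = f["circles"][()]
        a = dict(f["meta"].attrs)
    grid = GridSpec(n_xy=int(a["n_xy"]), fov_xy=float(a["fov_xy"]),
                    n_z=int(a["n_z"]),
                    fov_z=float(a["fov_z"]) or None)
    circles = [CircleSpec(kz_index=int(row[0]), r_c=row[1], phi_c=row[2],
                          R=row[3], theta0=row[4]) for row in tab]
    seed = int(a["seed"])
    warn = str(a.get("warnings", ""))
    return TrajectoryPlan(grid=grid, circles=circles,
                          samples_per_rev=int(a["samples_per_rev"]),
                          sbw=float(a["sbw"]), n_time=int(a["n_time"]),
                          family=str(a["family"]), af=float(a["af"]),
                          seed=None if seed < 0 else seed,
                          warnings=[w for w in warn.split("\n") if w])


def dump_circles_csv(plan: TrajectoryPlan, path) -> None:
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(_CIRCLE_COLUMNS)
        for row in _circle_table(plan):
            writer.writerow([int(row[0]), *row[1:]])


def save_kdata(kdata: SpectroKData, path) -> None:
    """k-space container: /kdata/values plus the plan under /plan."""
    with h5py.File(path, "w") as f:
        g = f.create_group("kdata")
        g.create_dataset("values", data=kdata.values)
        g.attrs["noise_sigma"] = kdata.noise_sigma
        g.attrs["seed"] = -1 if kdata.seed is None else kdata.seed
    with h5py.File(path, "a") as f:
        plan_grp = f.create_group("plan")
        plan_grp.create_dataset("circles", data=_circle_table(kdata.plan))
        plan_grp.create_dataset("k_samples", data=sample_points(kdata.plan))
        meta = plan_grp.create_group("meta")
        p = kdata.plan
        meta.attrs.update({
            "n_xy": p.grid.n_xy, "n_z": p.grid.n_z, "fov_xy": p.grid.fov_xy,
            "fov_z": p.grid.fov_z or 0.0, "samples_per_rev": p.samples_per_rev,
            "sbw": p.sbw, "n_time": p.n_time, "family": p.family, "af": p.af,
            "seed": -1 if p.seed is None else p.seed,
        })


def load_kdata(path) -> SpectroKData:
    with h5py.File(path, "r") as f:
        values = f["kdata/values"][()]
        sigma = float(f["kdata"].attrs["noise_sigma"])
        seed = int(f["kdata"].attrs["seed"])
        tab = f["plan/circles"][()]
        a = dict(f["plan/meta"].attrs)
    grid = GridSpec(n_xy=int(a["n_xy"]), fov_xy=float(a["fov_xy"]),
                    n_z=int(a["n_z"]), fov_z=float(a["fov_z"]) or None)
    circles = [CircleSpec(kz_index=int(r[0]), r_c=r[1], phi_c=r[2], R=r[3],
                          theta0=r[4]) for r in tab]
    pseed = int(a["seed"])
    plan = TrajectoryPlan(grid=grid, circles=circles,
                          samples_per_rev=int(a["samples_per_rev"]),
                          sbw=float(a["sbw"]), n_time=int(a["n_time"]),
                          family=str(a["family"]), af=float(a["af"]),
                          seed=None if pseed < 0 else pseed)
    return SpectroKData(values=values, plan=plan, noise_sigma=sigma,
                        seed=None if seed < 0 else seed)


def save_voxel_spectrum_csv(rho: np.ndarray, i: int, j: int, sbw: float,
                            path) -> None:
    """Dump one voxel's spectrum (frequency, real, imag, magnitude) as CSV."""
    fid = np.asarray(rho)[i, j, :]
    spec = np.fft.fftshift(np.fft.fft(fid))
    freqs = np.fft.fftshift(np.fft.fftfreq(fid.size, d=1.0 / sbw))
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["freq_hz", "real", "imag", "magnitude"])
        for fr, v in zip(freqs, spec):
            writer.writerow([fr, v.real, v.imag, abs(v)])


def save_map_nifti(image: np.ndarray, path, voxel_size_mm: float = 1.0) -> None:
    """Write a (possibly complex) map as NIfTI; complex maps go out as
    magnitude with a paired ``*_phase`` file."""
    img = np.asarray(image)
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    if np.iscomplexobj(img):
        nib.save(nib.Nifti1Image(np.abs(img).astype(np.float32), affine), str(path))
        ppath = str(path).replace(".nii", "_phase.nii")
        nib.save(nib.Nifti1Image(np.angle(img).astype(np.float32), affine), ppath)
    else:
        nib.save(nib.Nifti1Image(img.astype(np.float32), affine), str(path))
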