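"""HDF5 raw-data container and NIfTI / CSV export.

The raw container stores everything needed to reconstruct an acquisition:
``/kdata`` (complex, Nt × Ns × Nc), ``/traj`` (Nt × Ns × 2), ``/angles``,
optional ``/dcf``, ``/coilmaps`` (Nc × N × N), ``/motion_truth`` and
``/motion_estimate`` (Nt × 3: tx_mm, ty_mm, theta_deg), and the sequence
(``/seq/flip_angles`` plus attributes).  Parametric maps are written as one
NIfTI per parameter with the pixel size in the affine.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .coils import CoilMaps
from .matching import ParametricMaps
from .motion import RigidMotionTrajectory
from .sequence import SequenceParams
from .simulate import KSpaceData
from .trajectory import RadialTrajectory

__all__ = [
    "save_raw",
    "load_raw",
    "save_motion_csv",
    "load_motion_csv",
    "save_maps_nifti",
    "save_map_montage",
]


def save_raw(
    path,
    data: KSpaceData,
    seq: SequenceParams,
    motion_truth: RigidMotionTrajectory | None = None,
    motion_estimate: RigidMotionTrajectory | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kdata", data=data.samples)
        f.create_dataset("traj", data=data.traj.coords)
        f.create_dataset("angles", data=data.traj.angles)
        if data.traj.dcf is not None:
            f.create_dataset("dcf", data=data.traj.dcf)
        f.create_dataset("coilmaps", data=data.coils.maps)
        f.attrs["matrix"] = data.traj.matrix
        f.attrs["fov_mm"] = data.coils.fov_mm
        g = f.create_group("seq")
        g.create_dataset("flip_angles", data=seq.flip_angles)
        g.attrs["tr_ms"] = seq.tr_ms
        g.attrs["te_ms"] = seq.te_ms
        g.attrs["invert"] = seq.invert
        for name, mot in (("motion_truth", motion_truth), ("motion_estimate", motion_estimate)):
            if mot is not None:
                f.create_dataset(name, data=mot.as_array())


def load_raw(path) -> tuple:
    """Load a raw container; returns (KSpaceData, SequenceParams, truth, estimate)."""
    with h5py.File(path, "r") as f:
        traj = RadialTrajectory(
            coords=f["traj"][:],
            angles=f["angles"][:],
            matrix=int(f.attrs["matrix"]),
            dcf=f["dcf"][:] if "dcf" in f else None,
        )
        coils = CoilMaps(maps=f["coilmaps"][:], fov_mm=float(f.attrs["fov_mm"]))
        data = KSpaceData(samples=f["kdata"][:], traj=traj, coils=coils)
        g = f["seq"]
        seq = SequenceParams(
            flip_angles=g["flip_angles"][:],
            tr_ms=float(g.attrs["tr_ms"]),
            te_ms=float(g.attrs["te_ms"]),
            invert=bool(g.attrs["invert"]),
        )
        motions = []
        for name in ("motion_truth", "motion_estimate"):
            if name in f:
                arr = f[name][:]
                motions.append(RigidMotionTrajectory(arr[:, 0], arr[:, 1], arr[:, 2]))
            else:
                motions.append(None)
    return data, seq, motions[0], motions[1]


def save_motion_csv(path, motion: RigidMotionTrajectory) -> None:
    arr = np.column_stack([np.arange(len(motion)), motion.as_array()])
    np.savetxt(
        path,
        arr,
        delimiter=",",
        header="timepoint,tx_mm,ty_mm,theta_deg",
        comments="",
        fmt=["%d", "%.6f", "%.6f", "%.6f"],
    )


def load_motion_csv(path) -> RigidMotionTrajectory:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return RigidMotionTrajectory(arr[:, 1], arr[:, 2], arr[:, 3])


def _affine(pixel_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = pixel_mm
    return aff


def save_maps_nifti(out_dir, maps: ParametricMaps, pixel_mm: float, prefix: str = "") -> list:
    """Write T1/T2/M0/correlation maps as individual NIfTI files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, arr in (
        ("t1_ms", maps.t1_ms),
        ("t2_ms", maps.t2_ms),
        ("m0", maps.m0_magnitude),
        ("correlation", maps.match_correlation),
    ):
        p = out_dir / f"{prefix}{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), _affine(pixel_mm)), p)
        written.append(p)
    return written


def save_map_montage(path, maps: ParametricMaps, title: str = "") -> None:
    """QC montage (PNG) of the four matched maps."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 4, figsize=(14, 4))
    for ax, (name, arr, vmax) in zip(
        axes,
        [
            ("T1 [ms]", maps.t1_ms, None),
            ("T2 [ms]", maps.t2_ms, None),
            ("M0", maps.m0_magnitude, None),
            ("correlation", maps.match_correlation, 1.0),
        ],
    ):
        im = ax.imshow(arr, cmap="viridis", vmax=vmax)
        ax.set_title(name)
        ax.axis("off")
        fig.colorbar(im, ax=ax, shrink=0.7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
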