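"""File formats: MRC volumes/images, point-pattern CSV, profile CSV, RABS HDF5.

MRC (mode 2, float32) goes through gemmi's CCP4/MRC map support; an
NPZ-style container is available as a fallback for arrays of any
dimension.  Radial profiles are two-column CSV with a JSON header comment;
RABS grids are HDF5 with the three axis vectors, the value array and
provenance attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .patterns import GridSignal, PointPattern
from .three_point import RabsGrid
from .two_point import RadialProfile

__all__ = [
    "write_mrc",
    "read_mrc",
    "write_npz_signal",
    "read_npz_signal",
    "write_pattern_csv",
    "read_pattern_csv",
    "write_profile_csv",
    "read_profile_csv",
    "write_rabs_h5",
    "read_rabs_h5",
    "write_resonance_csv",
]


# ---------------------------------------------------------------------------
# volumes / images


def write_mrc(path, signal: GridSignal) -> None:
    """Write a 2D image or 3D volume as an MRC/CCP4 map (mode 2 float32)."""
    import gemmi

    vals = signal.values
    if vals.ndim == 2:
        vals = vals[:, :, None]
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(vals, dtype=np.float32))
    a, b, c = (n * signal.spacing for n in vals.shape)
    m.grid.unit_cell = gemmi.UnitCell(a, b, c, 90.0, 90.0, 90.0)
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path) -> GridSignal:
    """Read an MRC/CCP4 map written by :func:`write_mrc`."""
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    vals = np.array(m.grid, copy=True, dtype=float)
    spacing = m.grid.unit_cell.a / vals.shape[0]
    if vals.ndim == 3 and vals.shape[2] == 1:
        vals = vals[:, :, 0]
    return GridSignal(vals, spacing)


def write_npz_signal(path, signal: GridSignal) -> None:
    np.savez(
        path,
        values=signal.values,
        spacing=signal.spacing,
        origin=np.array(signal.origin),
    )


def read_npz_signal(path) -> GridSignal:
    with np.load(path) as z:
        return GridSignal(
            z["values"], float(z["spacing"]), tuple(int(o) for o in z["origin"])
        )


# ---------------------------------------------------------------------------
# point patterns: CSV columns x,y[,z],amplitude + JSON sidecar {R, dim}


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".json")


def write_pattern_csv(path, pattern: PointPattern) -> None:
    cols = ["x", "y", "z"][: pattern.dim]
    df = pd.DataFrame(pattern.centers, columns=cols)
    df["amplitude"] = pattern.amplitudes
    df.to_csv(path, index=False)
    _sidecar(path).write_text(
        json.dumps({"R": pattern.R, "dim": pattern.dim}, indent=2)
    )


def read_pattern_csv(path) -> PointPattern:
    meta = json.loads(_sidecar(path).read_text())
    df = pd.read_csv(path)
    cols = ["x", "y", "z"][: int(meta["dim"])]
    centers = df[cols].to_numpy(dtype=float)
    amps = (
        df["amplitude"].to_numpy(dtype=float)
        if "amplitude" in df
        else None
    )
    return PointPattern(centers, float(meta["R"]), amps)


# ---------------------------------------------------------------------------
# radial profiles: CSV with a JSON header comment


def write_profile_csv(path, profile: RadialProfile) -> None:
    header = json.dumps(
        {"dim": profile.dim, "space": profile.space, "meta": profile.meta}
    )
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        pd.DataFrame(
            {"radius": profile.radii, "value": profile.values}
        ).to_csv(fh, index=False)


def read_profile_csv(path) -> RadialProfile:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError("missing JSON header line")
        meta = json.loads(first[2:])
        df = pd.read_csv(fh)
    return RadialProfile(
        df["radius"].to_numpy(float),
        df["value"].to_numpy(float),
        int(meta["dim"]),
        meta["space"],
        meta.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# RABS grids: HDF5


def write_rabs_h5(path, rg: RabsGrid) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("L1", data=rg.L1)
        f.create_dataset("L2", data=rg.L2)
        f.create_dataset("theta", data=rg.theta)
        f.create_dataset("values", data=rg.values)
        f.attrs["space"] = rg.space
        f.attrs["meta"] = json.dumps(rg.meta, default=str)


def read_rabs_h5(path) -> RabsGrid:
    with h5py.File(path, "r") as f:
        return RabsGrid(
            f["L1"][:],
            f["L2"][:],
            f["theta"][:],
            f["values"][:],
            f.attrs["space"],
            json.loads(f.attrs["meta"]),
        )


# ---------------------------------------------------------------------------
# resonance maps: CSV matrix with JSON header


def write_resonance_csv(path, rm) -> None:
    header = json.dumps({"truth": rm.truth}, default=str)
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df = pd.DataFrame(
            rm.values,
            index=pd.Index(rm.radii, name="radius"),
            columns=[f"pitch_{p:g}" for p in rm.pitches],
        )
        df.to_csv(fh)
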