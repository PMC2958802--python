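"""Trajectory and field input/output.

Trajectories come in through standard MD containers (multi-model PDB and
DCD, via mdtraj) or through a delimited-text fixture format designed to
be inspectable and diff-able in tests.  Internally everything is Å and
ps; mdtraj's nm are converted on the way in and out.

Fixture format: one header line
    n_waters frame_interval_ps box_x box_y box_z unwrapped_flag
followed by one ``x y z`` line per atom per frame (frames outer, waters
inner, site order O H1 H2).

Fields are exported as delimited text, one row per cell
(``i j k value n_samples mask``) with the grid and units in ``#`` header
lines; masked values are written as ``NA``.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    FieldSlice,
    GridSpec,
    ScalarField,
    SolvmapError,
    TopologyError,
    TrajectoryEnsemble,
    WaterTopology,
)

__all__ = [
    "load_trajectories",
    "read_fixture",
    "write_fixture",
    "write_pdb",
    "write_dcd",
    "write_field",
    "read_field",
    "write_slice_matrix",
]

_NM_PER_ANGSTROM = 0.1
MASK_SENTINEL = "NA"


def read_fixture(path: str | os.PathLike) -> tuple[np.ndarray, float, np.ndarray, bool, int]:
    """Read one fixture trajectory; returns (coords, dt, box, unwrapped, n_waters)."""
    path = Path(path)
    try:
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 6:
                raise SolvmapError(
                    f"{path}: fixture header must have 6 fields "
                    "(n_waters dt box_x box_y box_z unwrapped)"
                )
            n_waters = int(header[0])
            dt = float(header[1])
            box = np.array([float(v) for v in header[2:5]])
            unwrapped = bool(int(header[5]))
            data = np.loadtxt(fh, ndmin=2)
    except OSError as exc:
        raise SolvmapError(f"cannot read trajectory file {path}: {exc}") from exc
    n_atoms = 3 * n_waters
    if data.shape[0] % n_atoms != 0 or data.shape[1] != 3:
        raise TopologyError(
            f"{path}: {data.shape[0]} atom lines not a multiple of "
            f"{n_atoms} atoms per frame ({n_waters} waters)"
        )
    n_frames = data.shape[0] // n_atoms
    coords = data.reshape(n_frames, n_waters, 3, 3)
    return coords, dt, box, unwrapped, n_waters


def write_fixture(path: str | os.PathLike, traj: np.ndarray, frame_interval: float,
                  box: np.ndarray, unwrapped: bool) -> None:
    """Write one trajectory (frames, waters, 3 sites, 3) to the fixture format."""
    n_frames, n_waters = traj.shape[:2]
    with open(path, "w") as fh:
        fh.write(
            f"{n_waters} {frame_interval:g} {box[0]:g} {box[1]:g} {box[2]:g} "
            f"{int(unwrapped)}\n"
        )
        flat = traj.reshape(n_frames * n_waters * 3, 3)
        np.savetxt(fh, flat, fmt="%.8g")


def _water_mdtraj_topology(n_waters: int):
    import mdtraj

    top = mdtraj.Topology()
    chain = top.add_chain()
    elem_O = mdtraj.element.oxygen
    elem_H = mdtraj.element.hydrogen
    for i in range(n_waters):
        res = top.add_residue("HOH", chain)
        top.add_atom("O", elem_O, res)
        top.add_atom("H1", elem_H, res)
        top.add_atom("H2", elem_H, res)
    return top


def write_pdb(path: str | os.PathLike, traj: np.ndarray, box: np.ndarray) -> None:
    """Write a trajectory as a multi-model PDB (coordinates in Å)."""
    import mdtraj

    n_frames, n_waters = traj.shape[:2]
    xyz = traj.reshape(n_frames, n_waters * 3, 3) * _NM_PER_ANGSTROM
    t = mdtraj.Trajectory(xyz, _water_mdtraj_topology(n_waters))
    t.unitcell_lengths = np.tile(np.asarray(box) * _NM_PER_ANGSTROM, (n_frames, 1))
    t.unitcell_angles = np.tile([90.0, 90.0, 90.0], (n_frames, 1))
    t.save_pdb(str(path))


def write_dcd(path: str | os.PathLike, traj: np.ndarray, box: np.ndarray) -> None:
    """Write a trajectory in DCD (binary) format."""
    import mdtraj

    n_frames, n_waters = traj.shape[:2]
    xyz = traj.reshape(n_frames, n_waters * 3, 3) * _NM_PER_ANGSTROM
    t = mdtraj.Trajectory(xyz, _water_mdtraj_topology(n_waters))
    t.unitcell_lengths = np.tile(np.asarray(box) * _NM_PER_ANGSTROM, (n_frames, 1))
    t.unitcell_angles = np.tile([90.0, 90.0, 90.0], (n_frames, 1))
    t.save_dcd(str(path))


def _load_mdtraj(path: Path, topology: WaterTopology, fmt: str) -> tuple[np.ndarray, np.ndarray]:
    import mdtraj

    top = _water_mdtraj_topology(topology.n_waters)
    try:
        if fmt == "pdb":
            t = mdtraj.load_pdb(str(path))
        else:
            t = mdtraj.load_dcd(str(path), top=top)
    except OSError as exc:
        raise SolvmapError(f"cannot read trajectory file {path}: {exc}") from exc
    if t.n_atoms != topology.n_sites:
        raise TopologyError(
            f"{path}: {t.n_atoms} atoms per frame, but topology declares "
            f"{topology.n_waters} waters ({topology.n_sites} sites)"
        )
    coords = t.xyz.reshape(t.n_frames, topology.n_waters, 3, 3) / _NM_PER_ANGSTROM
    if t.unitcell_lengths is None:
        raise SolvmapError(f"{path}: no box information in trajectory")
    box = t.unitcell_lengths[0] / _NM_PER_ANGSTROM
    return np.ascontiguousarray(coords, dtype=float), box


def load_trajectories(
    paths: Sequence[str | os.PathLike],
    topology: WaterTopology,
    format: str = "fixture",
    frame_interval: float | None = None,
    unwrapped: bool = False,
) -> TrajectoryEnsemble:
    """Read a set of trajectory files into one ensemble.

    Parameters
    ----------
    paths
        Trajectory files, one independent trajectory each.
    topology
        The shared water topology; atom counts are checked against it.
    format
        'fixture' (internal delimited text), 'pdb' (multi-model) or 'dcd'.
    frame_interval
        Frame spacing in ps; required for pdb/dcd (those containers do
        not carry it), read from the header for fixtures.
    unwrapped
        Declare pdb/dcd coordinates already unwrapped; fixtures carry
        their own flag.
    """
    fmt = format.lower()
    if fmt not in ("fixture", "txt", "pdb", "dcd"):
        raise SolvmapError(f"unsupported trajectory format {format!r}")
    if not paths:
        raise SolvmapError("no trajectory files given")
    coords_list: list[np.ndarray] = []
    dt: float | None = frame_interval
    box: np.ndarray | None = None
    unwrapped_flag = unwrapped
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise SolvmapError(f"cannot read trajectory file {p}: no such file")
        if fmt in ("fixture", "txt"):
            coords, file_dt, file_box, file_unwrapped, n_waters = read_fixture(p)
            if n_waters != topology.n_waters:
                raise TopologyError(
                    f"{p}: file declares {n_waters} waters, topology declares "
                    f"{topology.n_waters}"
                )
            if dt is None:
                dt = file_dt
            elif abs(dt - file_dt) > 1e-9:
                raise SolvmapError(
                    f"{p}: frame interval {file_dt} ps differs from ensemble "
                    f"interval {dt} ps"
                )
            unwrapped_flag = file_unwrapped
        else:
            coords, file_box = _load_mdtraj(p, topology, fmt)
            if dt is None:
                raise SolvmapError(
                    f"frame_interval is required for format {fmt!r}"
                )
        if box is None:
            box = file_box
        coords_list.append(coords)
    assert dt is not None and box is not None
    return TrajectoryEnsemble(
        topology=topology,
        coords=coords_list,
        frame_interval=dt,
        box=box,
        unwrapped=unwrapped_flag,
    )


def write_field(path: str | os.PathLike, field: ScalarField, name: str = "field") -> None:
    """Export a scalar field as delimited text, one row per cell."""
    g = field.grid
    with open(path, "w") as fh:
        fh.write(f"# solvmap-field name={name} units={field.units}\n")
        fh.write(
            f"# grid origin={g.origin[0]:g},{g.origin[1]:g},{g.origin[2]:g} "
            f"spacing={g.spacing:g} dims={g.dims[0]},{g.dims[1]},{g.dims[2]}\n"
        )
        for key, val in sorted(field.meta.items()):
            fh.write(f"# meta {key}={val}\n")
        fh.write("# columns: i j k value n_samples mask\n")
        nx, ny, nz = g.dims
        idx = np.indices(g.dims).reshape(3, -1).T
        vals = field.values.ravel()
        ns = field.n_samples.ravel()
        mk = field.mask.ravel()
        for (i, j, k), v, n, m in zip(idx, vals, ns, mk):
            vs = f"{v:.10g}" if m else MASK_SENTINEL
            fh.write(f"{i} {j} {k} {vs} {int(n)} {int(m)}\n")


def read_field(path: str | os.PathLike) -> ScalarField:
    """Read a scalar field written by :func:`write_field` (bit-exact round trip)."""
    units = ""
    grid: GridSpec | None = None
    meta: dict = {}
    rows: list[tuple[int, int, int, float, int, bool]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "solvmap-field" in line:
                    for tok in line.split():
                        if tok.startswith("units="):
                            units = tok[len("units="):]
                elif line.startswith("# grid"):
                    parts = dict(tok.split("=", 1) for tok in line[6:].split())
                    origin = tuple(float(v) for v in parts["origin"].split(","))
                    spacing = float(parts["spacing"])
                    dims = tuple(int(v) for v in parts["dims"].split(","))
                    grid = GridSpec(origin=origin, spacing=spacing, dims=dims)
                elif line.startswith("# meta "):
                    key, val = line[len("# meta "):].split("=", 1)
                    meta[key] = val
                continue
            i, j, k, v, n, m = line.split()
            mask = bool(int(m))
            rows.append((int(i), int(j), int(k), float(v) if mask else np.nan, int(n), mask))
    if grid is None:
        raise SolvmapError(f"{path}: missing grid header")
    values = np.full(grid.dims, np.nan)
    n_samples = np.zeros(grid.dims, dtype=np.int64)
    mask = np.zeros(grid.dims, dtype=bool)
    for i, j, k, v, n, m in rows:
        values[i, j, k] = v
        n_samples[i, j, k] = n
        mask[i, j, k] = m
    return ScalarField(grid, values, n_samples, mask, units, meta)


def write_slice_matrix(path: str | os.PathLike, sl: FieldSlice | np.ndarray,
                       mask: np.ndarray | None = None, header: str = "") -> None:
    """Write a 2-D slice as a tab-delimited matrix; masked cells become NA."""
    if isinstance(sl, FieldSlice):
        values, mask = sl.values, sl.mask
    else:
        values = sl
        if mask is None:
            mask = np.isfinite(values)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for row, mrow in zip(values, mask):
            fh.write(
                "\t".join(f"{v:.10g}" if m else MASK_SENTINEL for v, m in zip(row, mrow))
                + "\n"
            )
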