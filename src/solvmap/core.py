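"""Domain types shared by every estimator.

The central objects are an ensemble of short independent trajectories of
rigid three-site waters, a regular 3-D grid over the simulation box, and
per-cell scalar/tensor fields carrying a value, a sample count and a
validity mask.  All coordinates are in Å, times in ps; thermodynamic
fields are in reduced units (k_BT for free energies, k_B for entropies)
so temperature never enters numerically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = [
    "SolvmapError",
    "TopologyError",
    "GridError",
    "GeometryError",
    "WaterTopology",
    "TrajectoryEnsemble",
    "GridSpec",
    "ScalarField",
    "TensorField",
    "Slab",
    "BulkReference",
    "FieldSlice",
    "assign_cells",
    "unwrap",
    "wrap_ensemble",
    "extract_slice",
    "TIP3P_CHARGES",
    "TIP3P_OH_LENGTH",
    "TIP3P_HOH_ANGLE",
]

#: TIP3P rigid three-site water: partial charges (e), O-H bond (Å), H-O-H angle (deg).
TIP3P_CHARGES = (-0.834, 0.417, 0.417)
TIP3P_OH_LENGTH = 0.9572
TIP3P_HOH_ANGLE = 104.52

_AXIS_NAMES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


class SolvmapError(Exception):
    """Base class for package errors."""


class TopologyError(SolvmapError):
    """Atom counts or charges inconsistent with the declared water topology."""


class GridError(SolvmapError):
    """Grid definition or grid/field mismatch errors."""


class GeometryError(SolvmapError):
    """Degenerate molecular geometry (e.g. hydrogen coincident with oxygen)."""


def axis_number(axis: int | str) -> int:
    try:
        return _AXIS_NAMES[axis if isinstance(axis, int) else axis.lower()]
    except KeyError:
        raise GridError(f"unknown axis {axis!r}; expected one of x, y, z or 0, 1, 2")


@dataclass(frozen=True)
class WaterTopology:
    """Rigid three-site water model: site order is (O, H1, H2) per molecule.

    Parameters
    ----------
    n_waters
        Number of water molecules per frame.
    charges
        Partial charges (q_O, q_H1, q_H2) in elementary charge units;
        must sum to zero so the molecular dipole is origin independent.
    oh_length
        O-H bond length in Å.
    hoh_angle
        H-O-H angle in degrees, strictly between 0 and 180.
    """

    n_waters: int
    charges: tuple[float, float, float] = TIP3P_CHARGES
    oh_length: float = TIP3P_OH_LENGTH
    hoh_angle: float = TIP3P_HOH_ANGLE

    def __post_init__(self) -> None:
        if self.n_waters < 1:
            raise TopologyError(f"n_waters must be >= 1, got {self.n_waters}")
        if abs(sum(self.charges)) > 1e-9:
            raise TopologyError(
                f"per-molecule net charge must be 0, got {sum(self.charges):g}"
            )
        if not 0.0 < self.hoh_angle < 180.0:
            raise TopologyError(
                f"H-O-H angle must lie in (0, 180) degrees, got {self.hoh_angle}"
            )
        if self.oh_length <= 0:
            raise TopologyError("O-H length must be positive")

    @property
    def n_sites(self) -> int:
        return 3 * self.n_waters

    def body_sites(self) -> np.ndarray:
        """Site coordinates of one water in its body frame, shape (3, 3).

        Oxygen at the origin, H-O-H bisector along +z, hydrogens in the
        x-z plane.  The molecular dipole then points along +z.
        """
        half = np.deg2rad(self.hoh_angle) / 2.0
        sites = np.zeros((3, 3))
        sites[1] = self.oh_length * np.array([np.sin(half), 0.0, np.cos(half)])
        sites[2] = self.oh_length * np.array([-np.sin(half), 0.0, np.cos(half)])
        return sites


@dataclass
class TrajectoryEnsemble:
    """Many independent trajectories sharing one topology and frame interval.

    ``coords[t]`` has shape (n_frames, n_waters, 3 sites, 3) in Å with
    site order (O, H1, H2).  Trajectories may differ in length.
    """

    topology: WaterTopology
    coords: list[np.ndarray]
    frame_interval: float
    box: np.ndarray
    unwrapped: bool = False

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError(f"frame interval must be > 0, got {self.frame_interval}")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths in Å")
        nw = self.topology.n_waters
        for i, c in enumerate(self.coords):
            if c.ndim != 4 or c.shape[1:] != (nw, 3, 3):
                raise TopologyError(
                    f"trajectory {i}: expected frames x {nw} waters x 3 sites x 3, "
                    f"got shape {c.shape}"
                )
            if not np.all(np.isfinite(c)):
                raise ValueError(f"trajectory {i}: non-finite coordinates")

    @property
    def n_trajectories(self) -> int:
        return len(self.coords)

    @property
    def n_frames(self) -> list[int]:
        return [c.shape[0] for c in self.coords]

    @property
    def total_observations(self) -> int:
        """Total (water, frame) observations pooled over trajectories."""
        return sum(self.n_frames) * self.topology.n_waters

    def oxygens(self) -> Iterator[np.ndarray]:
        """Yield per-trajectory oxygen coordinates, shape (n_frames, n_waters, 3)."""
        for c in self.coords:
            yield c[:, :, 0, :]

    def subset(self, indices: Sequence[int]) -> "TrajectoryEnsemble":
        """Sub-ensemble of the given trajectory indices (arrays are shared)."""
        return TrajectoryEnsemble(
            topology=self.topology,
            coords=[self.coords[i] for i in indices],
            frame_interval=self.frame_interval,
            box=self.box,
            unwrapped=self.unwrapped,
        )


@dataclass(frozen=True)
class GridSpec:
    """Regular orthorhombic cell lattice; cells are half-open [lo, lo+h) per axis."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise GridError(f"grid spacing must be > 0, got {self.spacing}")
        if any(d < 1 for d in self.dims):
            raise GridError(f"grid dims must be >= 1 per axis, got {self.dims}")

    @classmethod
    def from_box(
        cls, box: Sequence[float], spacing: float = 1.0, origin: Sequence[float] = (0.0, 0.0, 0.0)
    ) -> "GridSpec":
        dims = tuple(int(np.floor(b / spacing + 1e-9)) for b in box)
        return cls(origin=tuple(float(o) for o in origin), spacing=float(spacing), dims=dims)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.dims))

    @property
    def origin_array(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    def edges(self, axis: int | str) -> np.ndarray:
        a = axis_number(axis)
        return self.origin[a] + self.spacing * np.arange(self.dims[a] + 1)

    def centers(self, axis: int | str) -> np.ndarray:
        a = axis_number(axis)
        return self.origin[a] + self.spacing * (np.arange(self.dims[a]) + 0.5)

    def cell_centers(self) -> np.ndarray:
        """Centers of all cells, shape dims + (3,)."""
        cx, cy, cz = (self.centers(a) for a in range(3))
        return np.stack(np.meshgrid(cx, cy, cz, indexing="ij"), axis=-1)

    def flatten_index(self, idx: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.dims
        return (idx[..., 0] * ny + idx[..., 1]) * nz + idx[..., 2]

    def span(self, axis: int | str) -> tuple[float, float]:
        a = axis_number(axis)
        return (self.origin[a], self.origin[a] + self.spacing * self.dims[a])


def assign_cells(positions: np.ndarray, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Map points to cell indices under the half-open cell convention.

    Returns ``(indices, inside)`` where ``indices`` has shape (..., 3) with
    ``i = floor((x - origin) / spacing)`` per axis and ``inside`` flags
    points falling within the grid.  Points outside are flagged, never
    clamped; their index values are meaningless.
    """
    positions = np.asarray(positions, dtype=float)
    rel = (positions - grid.origin_array) / grid.spacing
    idx = np.floor(rel).astype(np.int64)
    dims = np.asarray(grid.dims)
    inside = np.all((idx >= 0) & (idx < dims), axis=-1)
    return idx, inside


@dataclass
class ScalarField:
    """Per-cell scalar values with sample counts and a validity mask.

    ``values`` are defined only where ``mask`` is true (NaN elsewhere).
    ``units`` declares the physical units ('counts', 'k_BT', 'k_B',
    'Debye^2', 'A^2/ps', 'rad^2/ps', ...).
    """

    grid: GridSpec
    values: np.ndarray
    n_samples: np.ndarray
    mask: np.ndarray
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = tuple(self.grid.dims)
        for name in ("values", "n_samples", "mask"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise GridError(f"{name} shape {arr.shape} != grid dims {shape}")
        if np.any(self.n_samples < 0):
            raise ValueError("n_samples must be >= 0")
        self.values = np.where(self.mask, self.values, np.nan)

    def masked_like(self, values: np.ndarray, units: str, extra_mask: np.ndarray | None = None) -> "ScalarField":
        mask = self.mask if extra_mask is None else (self.mask & extra_mask)
        return ScalarField(self.grid, values, self.n_samples.copy(), mask, units, dict(self.meta))


@dataclass
class TensorField:
    """Per-cell symmetric 3x3 dipole covariance in Debye^2."""

    grid: GridSpec
    values: np.ndarray
    n_samples: np.ndarray
    mask: np.ndarray
    units: str = "Debye^2"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = tuple(self.grid.dims)
        if self.values.shape != shape + (3, 3):
            raise GridError(
                f"tensor values shape {self.values.shape} != grid dims {shape} + (3, 3)"
            )
        self.values = np.where(self.mask[..., None, None], self.values, np.nan)


@dataclass(frozen=True)
class Slab:
    """Axis-aligned slab spanning the full cross-section: lo <= coord < hi along `axis`."""

    axis: int | str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.hi <= self.lo:
            raise GridError(f"slab requires lo < hi, got [{self.lo}, {self.hi})")

    def cell_selector(self, grid: GridSpec) -> np.ndarray:
        """Boolean array over grid cells fully inside the slab."""
        a = axis_number(self.axis)
        edges = grid.edges(a)
        layer = (edges[:-1] >= self.lo - 1e-9) & (edges[1:] <= self.hi + 1e-9)
        sel = np.zeros(grid.dims, dtype=bool)
        index = [slice(None)] * 3
        index[a] = layer
        sel[tuple(index)] = True
        return sel


@dataclass(frozen=True)
class BulkReference:
    """Bulk slab plus the mean/sd of a field over its unmasked cells."""

    region: Slab
    mean: float
    sd: float
    n_cells: int


@dataclass
class FieldSlice:
    """One grid layer of a 3-D field along a chosen axis."""

    axis: int
    index: int
    coordinate: float
    values: np.ndarray
    n_samples: np.ndarray
    mask: np.ndarray
    units: str


def unwrap(ensemble: TrajectoryEnsemble) -> TrajectoryEnsemble:
    """Undo periodic wrapping so each molecule traces a continuous path.

    Works per molecule on consecutive frames under the minimum-image
    convention, using the oxygen to detect boundary crossings and shifting
    all three sites together so the rigid geometry is preserved.  Input
    that declares itself already unwrapped is returned unchanged.
    """
    if ensemble.unwrapped:
        return ensemble
    box = ensemble.box
    out: list[np.ndarray] = []
    for t, traj in enumerate(ensemble.coords):
        ox = traj[:, :, 0, :]
        d = np.diff(ox, axis=0)
        jumps = np.round(d / box)
        shift = -np.cumsum(jumps, axis=0) * box
        shift = np.concatenate([np.zeros_like(shift[:1]), shift], axis=0)
        fixed = traj + shift[:, :, None, :]
        if np.any(np.abs(np.diff(fixed[:, :, 0, :], axis=0)) > box / 2 + 1e-9):
            warnings.warn(
                f"trajectory {t}: frame-to-frame jump exceeds half the box after "
                "unwrapping; dynamics may be undersampled",
                stacklevel=2,
            )
        out.append(fixed)
    return replace(ensemble, coords=out, unwrapped=True)


def wrap_ensemble(ensemble: TrajectoryEnsemble) -> TrajectoryEnsemble:
    """Wrap each molecule (as a unit, by its oxygen) into [0, box) per axis."""
    box = ensemble.box
    out = []
    for traj in ensemble.coords:
        ox = traj[:, :, 0, :]
        shift = -np.floor(ox / box) * box
        out.append(traj + shift[:, :, None, :])
    return replace(ensemble, coords=out, unwrapped=False)


def extract_slice(field: ScalarField, axis: int | str, coordinate: float) -> FieldSlice:
    """The single layer of cells containing `coordinate` along `axis`."""
    a = axis_number(axis)
    lo, hi = field.grid.span(a)
    if not lo <= coordinate < hi:
        raise GridError(
            f"slice coordinate {coordinate} outside grid span [{lo}, {hi}) on axis {a}"
        )
    index = int(np.floor((coordinate - field.grid.origin[a]) / field.grid.spacing))
    sl = [slice(None)] * 3
    sl[a] = index
    sl = tuple(sl)
    return FieldSlice(
        axis=a,
        index=index,
        coordinate=coordinate,
        values=field.values[sl].copy(),
        n_samples=field.n_samples[sl].copy(),
        mask=field.mask[sl].copy(),
        units=field.units,
    )
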