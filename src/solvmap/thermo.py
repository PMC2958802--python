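"""Per-cell thermodynamic estimators.

Three spatially-resolved quantities characterize how a confining cavity
perturbs its solvent:

* the solvation potential of mean force, obtained by Boltzmann inversion
  of the oxygen-position histogram, W(r) = -ln(N(r)/N_bulk) in k_BT;
* the rotational entropy S(r) = -sum_i p_i ln p_i in k_B over 28 discrete
  orientational states — the unordered pair of lab-frame sign-octants
  (relative to the oxygen) containing the two hydrogens;
* the dipole fluctuation tensor C_ab(r) = <mu_a mu_b> - <mu_a><mu_b> in
  Debye^2, a proxy for local dielectric susceptibility where the Kirkwood
  formula does not apply, summarized by its trace and by the sum of its
  six off-diagonal entries.

All estimators pool (water, frame) observations over the ensemble's
independent trajectories, bin them on the grid, and mask cells with
fewer than ``min_samples`` observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    BulkReference,
    GeometryError,
    GridSpec,
    ScalarField,
    Slab,
    SolvmapError,
    TensorField,
    TrajectoryEnsemble,
    WaterTopology,
)

__all__ = [
    "N_ROTATIONAL_STATES",
    "OVERFLOW_STATE",
    "DEBYE_PER_E_ANGSTROM",
    "DEFAULT_MIN_SAMPLES",
    "RotationalState",
    "DipoleSample",
    "octant_index",
    "pair_state_index",
    "rotational_state",
    "rotational_states",
    "molecular_dipole",
    "molecular_dipoles",
    "count_field",
    "bulk_reference",
    "pmf_field",
    "rotational_entropy_field",
    "dipole_fluctuation_tensor_field",
    "tensor_trace_field",
    "offdiagonal_sum_field",
]

#: 8 octants choose 2 hydrogens: 28 regular orientational states.
N_ROTATIONAL_STATES = 28
#: Reserved label for the degenerate both-hydrogens-in-one-octant case,
#: unreachable for rigid waters with H-O-H > 90 degrees.
OVERFLOW_STATE = 28

#: 1 e*Angstrom in Debye.
DEBYE_PER_E_ANGSTROM = 4.803204

DEFAULT_MIN_SAMPLES = 100

# Rank of the unordered pair {i < j} in lexicographic enumeration.
_PAIR_RANK = np.full((8, 8), OVERFLOW_STATE, dtype=np.int64)
for _i in range(8):
    for _j in range(_i + 1, 8):
        _r = _i * 7 - _i * (_i - 1) // 2 + (_j - _i - 1)
        _PAIR_RANK[_i, _j] = _r
        _PAIR_RANK[_j, _i] = _r


@dataclass(frozen=True)
class RotationalState:
    """Canonical index of an unordered pair of distinct octants (0..27).

    Index 28 is the overflow label for the same-octant degeneracy.
    """

    index: int

    def __post_init__(self) -> None:
        if not 0 <= self.index <= OVERFLOW_STATE:
            raise ValueError(f"state index must lie in [0, {OVERFLOW_STATE}]")

    @property
    def is_overflow(self) -> bool:
        return self.index == OVERFLOW_STATE

    @property
    def octant_pair(self) -> tuple[int, int]:
        if self.is_overflow:
            raise ValueError("overflow state has no octant pair")
        i, j = np.argwhere(_PAIR_RANK == self.index)[0]
        return int(min(i, j)), int(max(i, j))


@dataclass(frozen=True)
class DipoleSample:
    """One molecular dipole observation attributed to a grid cell."""

    mu: tuple[float, float, float]
    cell: tuple[int, int, int]
    trajectory: int
    frame: int


def octant_index(v: np.ndarray) -> np.ndarray | int:
    """Sign-octant of an H-O displacement: 4*[x>=0] + 2*[y>=0] + [z>=0].

    Components exactly at zero tie to the non-negative side.  Vectorized
    over leading dimensions; a zero vector is degenerate geometry.
    """
    v = np.asarray(v, dtype=float)
    scalar = v.ndim == 1
    vv = v.reshape(-1, 3)
    if np.any(np.all(vv == 0.0, axis=-1)):
        raise GeometryError("zero H-O displacement: degenerate geometry")
    idx = 4 * (vv[:, 0] >= 0) + 2 * (vv[:, 1] >= 0) + (vv[:, 2] >= 0)
    idx = idx.astype(np.int64)
    return int(idx[0]) if scalar else idx.reshape(v.shape[:-1])


def pair_state_index(i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Canonical index of the unordered octant pair {i, j}; i == j -> overflow."""
    return _PAIR_RANK[np.asarray(i), np.asarray(j)]


def rotational_state(O: np.ndarray, H1: np.ndarray, H2: np.ndarray) -> RotationalState:
    """Orientational state of one water from its three site positions."""
    d1 = np.asarray(H1, dtype=float) - np.asarray(O, dtype=float)
    d2 = np.asarray(H2, dtype=float) - np.asarray(O, dtype=float)
    return RotationalState(int(pair_state_index(octant_index(d1), octant_index(d2))))


def rotational_states(coords: np.ndarray) -> np.ndarray:
    """Vectorized state assignment for water site arrays (..., 3 sites, 3)."""
    d1 = coords[..., 1, :] - coords[..., 0, :]
    d2 = coords[..., 2, :] - coords[..., 0, :]
    return pair_state_index(octant_index(d1), octant_index(d2))


def molecular_dipole(O: np.ndarray, H1: np.ndarray, H2: np.ndarray,
                     topology: WaterTopology) -> np.ndarray:
    """Molecular dipole in Debye, mu = sum_site q (r_site - r_O) * 4.803204.

    Origin independent because the per-molecule net charge is zero (the
    oxygen is used as the reference point for numerical convenience).
    """
    if abs(sum(topology.charges)) > 1e-9:
        raise SolvmapError("net molecular charge must be zero for an origin-free dipole")
    qO, q1, q2 = topology.charges
    O = np.asarray(O, dtype=float)
    mu = q1 * (np.asarray(H1, dtype=float) - O) + q2 * (np.asarray(H2, dtype=float) - O)
    return mu * DEBYE_PER_E_ANGSTROM


def molecular_dipoles(coords: np.ndarray, topology: WaterTopology) -> np.ndarray:
    """Dipoles for water site arrays (..., 3 sites, 3) -> (..., 3) in Debye."""
    return molecular_dipole(coords[..., 0, :], coords[..., 1, :], coords[..., 2, :], topology)


def _pooled_flat_cells(ensemble: TrajectoryEnsemble, grid: GridSpec):
    """Flat cell index per pooled in-grid oxygen observation + out-of-grid count.

    Yields (flat_index, inside_count, per-trajectory slices) lazily per
    trajectory to keep memory bounded.
    """
    from .core import assign_cells

    for traj in ensemble.coords:
        ox = traj[:, :, 0, :].reshape(-1, 3)
        idx, inside = assign_cells(ox, grid)
        yield traj, grid.flatten_index(idx[inside]), inside


def count_field(ensemble: TrajectoryEnsemble, grid: GridSpec) -> ScalarField:
    """3-D histogram of oxygen positions pooled over all trajectories.

    ``meta['out_of_grid']`` records observations falling outside the grid
    (they are excluded, never clamped).  Conservation: sum of counts plus
    out-of-grid equals n_waters x total frames.
    """
    if ensemble.n_trajectories == 0:
        raise SolvmapError("empty ensemble")
    counts = np.zeros(grid.n_cells, dtype=np.int64)
    out_of_grid = 0
    for _traj, flat, inside in _pooled_flat_cells(ensemble, grid):
        counts += np.bincount(flat, minlength=grid.n_cells)
        out_of_grid += int(inside.size - inside.sum())
    counts = counts.reshape(grid.dims)
    return ScalarField(
        grid=grid,
        values=counts.astype(float),
        n_samples=counts,
        mask=np.ones(grid.dims, dtype=bool),
        units="counts",
        meta={"out_of_grid": out_of_grid},
    )


def bulk_reference(field: ScalarField, region: Slab,
                   min_samples: int = 0) -> BulkReference:
    """Mean and sd of a field over unmasked cells fully inside the slab.

    The sd is the spatial spread across bulk cells (ddof=1), the only
    bulk statistic available for defining 'within one standard deviation
    of the bulk value' classification bands.  ``min_samples`` restricts
    the average to cells with at least that many observations, so a
    count-field normalization can use exactly the cells the derived PMF
    will keep.
    """
    sel = region.cell_selector(field.grid) & field.mask
    if min_samples > 0:
        sel &= field.n_samples >= min_samples
    n = int(sel.sum())
    if n == 0:
        raise SolvmapError("no unmasked cells inside the bulk region")
    vals = field.values[sel]
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return BulkReference(region=region, mean=float(np.mean(vals)), sd=sd, n_cells=n)


def pmf_field(counts: ScalarField, bulk: BulkReference,
              min_samples: int = DEFAULT_MIN_SAMPLES) -> ScalarField:
    """Potential of mean force by Boltzmann inversion, W(r) = -ln(N(r)/N_bulk).

    Reported in k_BT.  Cells with zero counts or fewer than ``min_samples``
    observations are masked (a zero count would give W = +inf, which says
    more about sampling than about free energy).  By construction the
    bulk-slab average of W is ~0.
    """
    if bulk.mean <= 0:
        raise SolvmapError("bulk mean count must be > 0 for Boltzmann inversion")
    n = counts.values
    with np.errstate(divide="ignore", invalid="ignore"):
        w = -np.log(n / bulk.mean)
    ok = counts.mask & (counts.n_samples >= max(min_samples, 1))
    field = counts.masked_like(w, units="k_BT", extra_mask=ok)
    field.meta["bulk_mean_count"] = bulk.mean
    return field


def rotational_entropy_field(ensemble: TrajectoryEnsemble, grid: GridSpec,
                             min_samples: int = DEFAULT_MIN_SAMPLES) -> ScalarField:
    """Shannon entropy of the octant-pair state distribution per cell, in k_B.

    S(r) = -sum_i p_i ln p_i over the 28 regular states with p_i the
    empirical frequency among in-cell observations (0 ln 0 := 0), so
    S is bounded by [0, ln 28 ~ 3.33 k_B].  Overflow (same-octant)
    observations cannot occur for rigid waters with H-O-H > 90 deg; if
    present they enter the normalization but carry no entropy term.
    """
    if ensemble.n_trajectories == 0:
        raise SolvmapError("empty ensemble")
    n_slots = OVERFLOW_STATE + 1
    state_counts = np.zeros(grid.n_cells * n_slots, dtype=np.int64)
    for traj, flat, inside in _pooled_flat_cells(ensemble, grid):
        states = rotational_states(traj.reshape(-1, 3, 3))[inside]
        state_counts += np.bincount(flat * n_slots + states,
                                    minlength=grid.n_cells * n_slots)
    state_counts = state_counts.reshape(grid.n_cells, n_slots)
    totals = state_counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = state_counts[:, :N_ROTATIONAL_STATES] / totals[:, None]
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    entropy = terms.sum(axis=1).reshape(grid.dims)
    n_samples = totals.reshape(grid.dims)
    mask = n_samples >= max(min_samples, 1)
    return ScalarField(
        grid=grid,
        values=entropy,
        n_samples=n_samples,
        mask=mask,
        units="k_B",
        meta={"overflow_observations": int(state_counts[:, OVERFLOW_STATE].sum())},
    )


def dipole_fluctuation_tensor_field(ensemble: TrajectoryEnsemble, grid: GridSpec,
                                    min_samples: int = DEFAULT_MIN_SAMPLES) -> TensorField:
    """Per-cell covariance of the molecular dipole vector, in Debye^2.

    C_ab(r) = <mu_a mu_b> - <mu_a><mu_b> over in-cell observations.
    Symmetric and positive semi-definite by construction (up to rounding).
    """
    if ensemble.n_trajectories == 0:
        raise SolvmapError("empty ensemble")
    n_cells = grid.n_cells
    s_mu = np.zeros((n_cells, 3))
    s_mumu = np.zeros((n_cells, 3, 3))
    n_obs = np.zeros(n_cells, dtype=np.int64)
    for traj, flat, inside in _pooled_flat_cells(ensemble, grid):
        mu = molecular_dipoles(traj.reshape(-1, 3, 3), ensemble.topology)[inside]
        n_obs += np.bincount(flat, minlength=n_cells)
        for a in range(3):
            s_mu[:, a] += np.bincount(flat, weights=mu[:, a], minlength=n_cells)
            for b in range(a, 3):
                s_mumu[:, a, b] += np.bincount(
                    flat, weights=mu[:, a] * mu[:, b], minlength=n_cells
                )
    for a in range(3):
        for b in range(a):
            s_mumu[:, a, b] = s_mumu[:, b, a]
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_mu = s_mu / n_obs[:, None]
        mean_mumu = s_mumu / n_obs[:, None, None]
        cov = mean_mumu - mean_mu[:, :, None] * mean_mu[:, None, :]
    mask = (n_obs >= max(min_samples, 1)).reshape(grid.dims)
    return TensorField(
        grid=grid,
        values=cov.reshape(grid.dims + (3, 3)),
        n_samples=n_obs.reshape(grid.dims),
        mask=mask,
    )


def tensor_trace_field(t: TensorField) -> ScalarField:
    """Trace C_xx + C_yy + C_zz of the dipole fluctuation tensor (>= 0)."""
    trace = np.einsum("...ii->...", np.nan_to_num(t.values))
    return ScalarField(t.grid, trace, t.n_samples.copy(), t.mask.copy(),
                       units="Debye^2", meta=dict(t.meta))


def offdiagonal_sum_field(t: TensorField) -> ScalarField:
    """Sum of the six off-diagonal tensor entries, = 2(C_xy + C_xz + C_yz).

    Reported with sign; nonzero values indicate that polarization along
    one axis is coupled to polarization along another, a signature of
    solvent ordering.
    """
    vals = np.nan_to_num(t.values)
    total = vals.sum(axis=(-2, -1)) - np.einsum("...ii->...", vals)
    return ScalarField(t.grid, total, t.n_samples.copy(), t.mask.copy(),
                       units="Debye^2", meta=dict(t.meta))
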