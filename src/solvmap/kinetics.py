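"""Position-resolved translational and rotational mobility.

Translational diffusion uses the Einstein relation at a single fixed lag
tau: a molecule is attributed to the grid cell it occupies at the start
of the lag window and contributes its squared displacement tau later,
giving D(r) = <|dr|^2>/(6 tau) and per-axis D_a(r) = <da^2>/(2 tau).

Rotational mobility is measured as Q(r) = <cos^2 theta(tau)> between the
molecular dipole at t and t + tau: 1 for frozen orientations, 1/3 once
fully decorrelated.  Under isotropic rotational Brownian motion the
second Legendre moment decays exponentially, <P2> = (3Q-1)/2 =
exp(-6 D_rot tau), which inverts Q into a rotational diffusion map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core import GridSpec, ScalarField, SolvmapError, TrajectoryEnsemble, assign_cells
from .thermo import DEFAULT_MIN_SAMPLES, molecular_dipoles

__all__ = [
    "LagSpec",
    "TranslationalDiffusion",
    "translational_diffusion_field",
    "rotational_decorrelation_field",
    "rotational_diffusion_field",
]


@dataclass(frozen=True)
class LagSpec:
    """Fixed observation lag tau in ps (default 50)."""

    tau: float = 50.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"lag must be > 0 ps, got {self.tau}")

    def frames(self, frame_interval: float) -> int:
        """Lag in frames; tau must be an integer multiple of the frame interval."""
        ratio = self.tau / frame_interval
        n = round(ratio)
        if n < 1 or abs(ratio - n) > 1e-6:
            raise ValueError(
                f"lag {self.tau} ps is not an integer multiple of the frame "
                f"interval {frame_interval} ps"
            )
        return n


class TranslationalDiffusion(NamedTuple):
    """Total and per-axis diffusion maps plus the raw mean-square displacement."""

    total: ScalarField           # A^2/ps, D = <|dr|^2> / 6 tau
    per_axis: tuple[ScalarField, ScalarField, ScalarField]  # D_a = <da^2> / 2 tau
    msd: ScalarField             # A^2


def _start_pairs(ensemble: TrajectoryEnsemble, lag_frames: int):
    """Yield (start oxygens, displaced site coords) per trajectory, skipping short ones."""
    for t, traj in enumerate(ensemble.coords):
        if traj.shape[0] <= lag_frames:
            warnings.warn(
                f"trajectory {t} has {traj.shape[0]} frames, shorter than the "
                f"{lag_frames}-frame lag; skipped",
                stacklevel=3,
            )
            continue
        yield traj[:-lag_frames], traj[lag_frames:]


def translational_diffusion_field(
    ensemble: TrajectoryEnsemble,
    grid: GridSpec,
    lag: LagSpec = LagSpec(),
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> TranslationalDiffusion:
    """Einstein-relation diffusion map at fixed lag, total and per axis.

    Every frame is used as a start; the (molecule, start-frame) pair is
    attributed to the cell containing the oxygen at the start of the lag
    window regardless of where the molecule ends up.  Requires unwrapped
    coordinates — squared displacements across a periodic wrap would be
    meaningless.
    """
    if not ensemble.unwrapped:
        raise SolvmapError(
            "translational diffusion needs unwrapped coordinates; call unwrap() first"
        )
    nlag = lag.frames(ensemble.frame_interval)
    n_cells = grid.n_cells
    s_d2 = np.zeros((n_cells, 3))
    n_obs = np.zeros(n_cells, dtype=np.int64)
    any_traj = False
    for start, end in _start_pairs(ensemble, nlag):
        any_traj = True
        o0 = start[:, :, 0, :].reshape(-1, 3)
        o1 = end[:, :, 0, :].reshape(-1, 3)
        idx, inside = assign_cells(o0, grid)
        flat = grid.flatten_index(idx[inside])
        d2 = (o1[inside] - o0[inside]) ** 2
        n_obs += np.bincount(flat, minlength=n_cells)
        for a in range(3):
            s_d2[:, a] += np.bincount(flat, weights=d2[:, a], minlength=n_cells)
    if not any_traj:
        raise SolvmapError("no trajectory is longer than the lag")
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_d2 = s_d2 / n_obs[:, None]
    mask = (n_obs >= max(min_samples, 1)).reshape(grid.dims)
    ns = n_obs.reshape(grid.dims)
    tau = lag.tau

    def _field(vals: np.ndarray, units: str) -> ScalarField:
        return ScalarField(grid, vals.reshape(grid.dims), ns.copy(), mask.copy(), units)

    msd = _field(mean_d2.sum(axis=1), "A^2")
    total = _field(mean_d2.sum(axis=1) / (6.0 * tau), "A^2/ps")
    per_axis = tuple(_field(mean_d2[:, a] / (2.0 * tau), "A^2/ps") for a in range(3))
    return TranslationalDiffusion(total=total, per_axis=per_axis, msd=msd)


def rotational_decorrelation_field(
    ensemble: TrajectoryEnsemble,
    grid: GridSpec,
    lag: LagSpec = LagSpec(),
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> ScalarField:
    """Q(r) = <cos^2 theta> between the dipole at t and t + tau, per start cell.

    Dimensionless in [0, 1]; insensitive to periodic wrapping because it
    uses orientations only, but start-cell attribution follows the same
    convention as translational diffusion.
    """
    nlag = lag.frames(ensemble.frame_interval)
    n_cells = grid.n_cells
    s_c2 = np.zeros(n_cells)
    n_obs = np.zeros(n_cells, dtype=np.int64)
    any_traj = False
    top = ensemble.topology
    for start, end in _start_pairs(ensemble, nlag):
        any_traj = True
        mu0 = molecular_dipoles(start.reshape(-1, 3, 3), top)
        mu1 = molecular_dipoles(end.reshape(-1, 3, 3), top)
        norm = np.linalg.norm(mu0, axis=1) * np.linalg.norm(mu1, axis=1)
        if np.any(norm == 0):
            raise SolvmapError("zero dipole moment: cannot measure orientation")
        cos = np.einsum("ij,ij->i", mu0, mu1) / norm
        idx, inside = assign_cells(start[:, :, 0, :].reshape(-1, 3), grid)
        flat = grid.flatten_index(idx[inside])
        n_obs += np.bincount(flat, minlength=n_cells)
        s_c2 += np.bincount(flat, weights=cos[inside] ** 2, minlength=n_cells)
    if not any_traj:
        raise SolvmapError("no trajectory is longer than the lag")
    with np.errstate(divide="ignore", invalid="ignore"):
        q = s_c2 / n_obs
    mask = (n_obs >= max(min_samples, 1)).reshape(grid.dims)
    return ScalarField(grid, q.reshape(grid.dims), n_obs.reshape(grid.dims),
                       mask, units="dimensionless", meta={"lag_ps": lag.tau})


def rotational_diffusion_field(q: ScalarField, lag: LagSpec = LagSpec()) -> ScalarField:
    """Invert a Q map into D_rot assuming isotropic rotational diffusion.

    <P2(tau)> = (3Q - 1)/2 = exp(-6 D_rot tau), so
    D_rot = -ln((3Q - 1)/2) / (6 tau) in rad^2/ps.  Cells already
    decorrelated beyond the model's range ((3Q-1)/2 <= 0) are masked.
    The raw Q field should always be kept alongside: it is model-free.
    """
    vals = q.values[q.mask]
    if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9):
        raise SolvmapError("Q values outside [0, 1]; not a cos^2 decorrelation field")
    with np.errstate(divide="ignore", invalid="ignore"):
        p2 = (3.0 * q.values - 1.0) / 2.0
        d_rot = -np.log(p2) / (6.0 * lag.tau)
    ok = q.mask & np.isfinite(q.values) & ((3.0 * np.nan_to_num(q.values) - 1.0) / 2.0 > 0)
    out = q.masked_like(d_rot, units="rad^2/ps", extra_mask=ok)
    out.meta["lag_ps"] = lag.tau
    return out
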