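"""Synthetic trajectory ensembles with known ground truth.

The estimators in this package assume a particular statistical structure
— many short independent trajectories of rigid three-site waters whose
positions diffuse (optionally in a known external potential) and whose
orientations either diffuse rotationally or are restricted to chosen
orientational states.  This module generates exactly that structure with
every parameter known, so each estimator can be validated by parameter
recovery: a Boltzmann sampler in a known well must be recovered by the
PMF, a known D_t by the Einstein map, a known D_rot by the Q inversion,
and restriction to k states must yield entropy ln k.

It is statistical ground truth, not physical water: particles do not
interact, there is no hydrogen bonding and no electrostatics.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Protocol

import numpy as np
from scipy.spatial.transform import Rotation

from .core import SolvmapError, TrajectoryEnsemble, WaterTopology, wrap_ensemble
from .thermo import N_ROTATIONAL_STATES, rotational_states

__all__ = [
    "Potential",
    "HarmonicWell",
    "CylindricalTunnel",
    "SyntheticSpec",
    "gen_ensemble",
    "gen_boltzmann_positions",
    "state_orientation_table",
    "toy_tunnel_spec",
]


class Potential(Protocol):
    """External potential in k_BT with analytic gradient (k_BT/A)."""

    def energy(self, points: np.ndarray) -> np.ndarray: ...

    def gradient(self, points: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class HarmonicWell:
    """Isotropic-or-not harmonic well, U = sum_a 0.5 k_a (x_a - c_a)^2 in k_BT.

    The Boltzmann-stationary density is Gaussian with per-axis variance
    1/k_a (in A^2, with k in k_BT/A^2).
    """

    center: tuple[float, float, float]
    k: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(ki < 0 for ki in self.k):
            raise ValueError("spring constants must be >= 0")

    def energy(self, points: np.ndarray) -> np.ndarray:
        d = np.asarray(points, dtype=float) - np.asarray(self.center)
        return 0.5 * (np.asarray(self.k) * d**2).sum(axis=-1)

    def gradient(self, points: np.ndarray) -> np.ndarray:
        d = np.asarray(points, dtype=float) - np.asarray(self.center)
        return np.asarray(self.k) * d


@dataclass(frozen=True)
class CylindricalTunnel:
    """Soft-walled cylindrical cavity opening into a bulk region.

    Along ``axis`` the cavity runs from the box floor to ``mouth``; in
    that range the solvent is confined radially by a harmonic wall of
    stiffness ``wall_k`` (k_BT/A^2) beyond ``radius``.  Past the mouth
    the cross-section is unconfined (bulk).  Soft harmonic walls of
    stiffness ``box_k`` keep particles inside the box on every axis.
    """

    box: tuple[float, float, float]
    axis: int = 2
    radius: float = 7.5
    wall_k: float = 2.0
    mouth: float = 40.0
    box_k: float = 5.0

    @property
    def _cross_axes(self) -> tuple[int, int]:
        return tuple(a for a in range(3) if a != self.axis)  # type: ignore[return-value]

    @property
    def _center(self) -> np.ndarray:
        return np.asarray([self.box[a] / 2.0 for a in self._cross_axes])

    def energy(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        u = np.zeros(p.shape[:-1])
        a1, a2 = self._cross_axes
        rho = np.hypot(p[..., a1] - self._center[0], p[..., a2] - self._center[1])
        over = np.clip(rho - self.radius, 0.0, None)
        in_tunnel = p[..., self.axis] < self.mouth
        u += np.where(in_tunnel, 0.5 * self.wall_k * over**2, 0.0)
        for a in range(3):
            below = np.clip(-p[..., a], 0.0, None)
            above = np.clip(p[..., a] - self.box[a], 0.0, None)
            u += 0.5 * self.box_k * (below**2 + above**2)
        return u

    def gradient(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        g = np.zeros_like(p)
        a1, a2 = self._cross_axes
        d1 = p[..., a1] - self._center[0]
        d2 = p[..., a2] - self._center[1]
        rho = np.hypot(d1, d2)
        over = np.clip(rho - self.radius, 0.0, None)
        in_tunnel = p[..., self.axis] < self.mouth
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(rho > 0, self.wall_k * over / rho, 0.0) * in_tunnel
        g[..., a1] += scale * d1
        g[..., a2] += scale * d2
        for a in range(3):
            g[..., a] += self.box_k * (
                np.clip(p[..., a] - self.box[a], 0.0, None) - np.clip(-p[..., a], 0.0, None)
            )
        return g


_ORIENTATION_MODES = ("free", "frozen", "uniform_states", "two_state_flip")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of a synthetic ensemble (the ground truth).

    Rates: ``d_t`` in A^2/ps (scalar or per-axis), ``d_rot`` in rad^2/ps.
    ``orientation_mode`` is one of 'free' (rotational Brownian motion),
    'frozen', 'uniform_states' (independent, balanced draws from
    ``n_states`` designated octant-pair states, giving entropy exactly
    ln k in the large-sample limit) or 'two_state_flip' (deterministic
    180-degree dipole flip every frame).
    """

    n_trajectories: int = 100
    n_frames: int = 200
    frame_interval: float = 1.0
    box: tuple[float, float, float] = (30.0, 30.0, 60.0)
    n_waters: int = 10
    d_t: float | tuple[float, float, float] = 0.2
    d_rot: float = 0.05
    potential: HarmonicWell | CylindricalTunnel | None = None
    orientation_mode: str = "free"
    n_states: int = N_ROTATIONAL_STATES
    states: tuple[int, ...] | None = None
    charges: tuple[float, float, float] = (-0.834, 0.417, 0.417)
    oh_length: float = 0.9572
    hoh_angle: float = 104.52
    seed: int = 0

    def __post_init__(self) -> None:
        if self.orientation_mode not in _ORIENTATION_MODES:
            raise SolvmapError(
                f"unknown orientation mode {self.orientation_mode!r}; "
                f"expected one of {_ORIENTATION_MODES}"
            )
        d = np.atleast_1d(np.asarray(self.d_t, dtype=float))
        if np.any(d < 0) or self.d_rot < 0:
            raise SolvmapError("diffusion rates must be >= 0")
        if not 1 <= self.n_states <= N_ROTATIONAL_STATES:
            raise SolvmapError(f"n_states must lie in [1, {N_ROTATIONAL_STATES}]")
        if self.states is not None and any(
            not 0 <= s < N_ROTATIONAL_STATES for s in self.states
        ):
            raise SolvmapError("designated states must lie in [0, 27]")
        if self.orientation_mode == "free" and self.d_rot * self.frame_interval > 0.1:
            raise SolvmapError(
                "d_rot * dt > 0.1: the small-angle rotational propagation is "
                "only valid for d_rot * dt << 1; reduce the frame interval"
            )

    @property
    def topology(self) -> WaterTopology:
        return WaterTopology(self.n_waters, self.charges, self.oh_length, self.hoh_angle)

    @property
    def d_t_vector(self) -> np.ndarray:
        d = np.asarray(self.d_t, dtype=float)
        return np.broadcast_to(d, (3,)).copy() if d.ndim else np.full(3, float(d))

    @property
    def state_list(self) -> tuple[int, ...]:
        if self.states is not None:
            return self.states
        return tuple(range(self.n_states))


def _uniform_rotations(rng: np.random.Generator, n: int) -> Rotation:
    """Uniform random rotations via normalized Gaussian quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return Rotation.from_quat(q)


_STATE_TABLE_CACHE: dict[tuple[float, float], np.ndarray] = {}


def state_orientation_table(topology: WaterTopology) -> np.ndarray:
    """One representative rigid-water orientation per octant-pair state.

    Returns rotation matrices of shape (28, 3, 3): applying matrix s to
    the body-frame sites puts the two hydrogens into the octant pair of
    canonical state s.  Built once per geometry by deterministic
    rejection over uniform orientations (every state is reachable for
    H-O-H angles away from the degenerate limits).
    """
    key = (topology.oh_length, topology.hoh_angle)
    if key in _STATE_TABLE_CACHE:
        return _STATE_TABLE_CACHE[key]
    body = topology.body_sites()
    rng = np.random.default_rng(900417)
    table = np.zeros((N_ROTATIONAL_STATES, 3, 3))
    found = np.zeros(N_ROTATIONAL_STATES, dtype=bool)
    for _ in range(200):
        mats = _uniform_rotations(rng, 2000).as_matrix()
        sites = np.einsum("pij,sj->psi", mats, body)
        states = rotational_states(sites)
        for s, m in zip(states, mats):
            if s < N_ROTATIONAL_STATES and not found[s]:
                table[s] = m
                found[s] = True
        if found.all():
            break
    if not found.all():
        raise SolvmapError(
            "could not find representative orientations for all 28 states; "
            "geometry too close to degenerate"
        )
    _STATE_TABLE_CACHE[key] = table
    return table


def gen_boltzmann_positions(
    potential: Potential | None,
    n: int,
    box: tuple[float, float, float],
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """I.i.d. draws from density ~ exp(-U(r)) on the box, by rejection.

    The envelope is uniform on the box scaled by exp(-U_min), with U_min
    probed on a coarse lattice.  Errors out if the acceptance rate drops
    below 1e-3 (the potential is then too sharp for a uniform envelope).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    box_arr = np.asarray(box, dtype=float)
    if potential is None:
        return rng.uniform(0.0, box_arr, size=(n, 3))
    probes = np.stack(
        np.meshgrid(*[np.linspace(0, b, 25) for b in box_arr], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    u_min = float(np.min(potential.energy(probes)))
    out = np.empty((n, 3))
    got = 0
    proposed = 0
    while got < n:
        m = max(4 * (n - got), 1000)
        cand = rng.uniform(0.0, box_arr, size=(m, 3))
        acc_p = np.exp(-(potential.energy(cand) - u_min))
        keep = cand[rng.uniform(size=m) < np.clip(acc_p, 0.0, 1.0)]
        take = min(len(keep), n - got)
        out[got:got + take] = keep[:take]
        got += take
        proposed += m
        if proposed > 10_000 and got / proposed < 1e-3:
            raise SolvmapError(
                "rejection acceptance rate < 1e-3; use a tighter envelope or "
                "a softer potential"
            )
    return out


def _propagate_orientations(spec: SyntheticSpec, rng: np.random.Generator,
                            n_particles: int) -> np.ndarray:
    """Rotation matrices for every (frame, particle), shape (F, P, 3, 3)."""
    F, P = spec.n_frames, n_particles
    mode = spec.orientation_mode
    if mode == "frozen":
        r0 = _uniform_rotations(rng, P).as_matrix()
        return np.broadcast_to(r0, (F, P, 3, 3)).copy()
    if mode == "uniform_states":
        table = state_orientation_table(spec.topology)[list(spec.state_list)]
        k = len(spec.state_list)
        # balanced round-robin: every cell visited by a particle cycles
        # through all k states equally, so occupancy is uniform by design
        frames = np.arange(F)[:, None]
        particles = np.arange(P)[None, :]
        draw = (frames + particles) % k
        return table[draw]
    if mode == "two_state_flip":
        # dipole (body +z) along lab +x on even frames, -x on odd frames
        base = Rotation.from_euler("y", 90, degrees=True).as_matrix()
        flip = np.diag([-1.0, -1.0, 1.0]) @ base
        mats = np.empty((F, P, 3, 3))
        mats[0::2] = base
        mats[1::2] = flip
        return mats
    # free rotational Brownian motion: compose small random rotations
    sigma = np.sqrt(2.0 * spec.d_rot * spec.frame_interval)
    mats = np.empty((F, P, 3, 3))
    current = _uniform_rotations(rng, P).as_matrix()
    mats[0] = current
    for f in range(1, F):
        if sigma > 0:
            step = Rotation.from_rotvec(rng.normal(0.0, sigma, size=(P, 3))).as_matrix()
            current = np.einsum("pij,pjk->pik", step, current)
        mats[f] = current
    return mats


def gen_ensemble(spec: SyntheticSpec, wrapped: bool = False) -> TrajectoryEnsemble:
    """Generate the ensemble described by a :class:`SyntheticSpec`.

    Translation is overdamped Langevin, dr = -D_t grad(U) dt +
    sqrt(2 D_t dt) N(0,1) per axis, started from the exact Boltzmann
    distribution of the potential (uniform when there is none) so the
    whole trajectory is stationary.  Hydrogens are rebuilt from the rigid
    body geometry every frame.  Same seed, same ensemble, bit for bit.
    Coordinates are emitted unwrapped; ``wrapped=True`` returns the
    periodic-wrapped duplicate instead.
    """
    rng = np.random.default_rng(spec.seed)
    topo = spec.topology
    F, T, W = spec.n_frames, spec.n_trajectories, spec.n_waters
    P = T * W
    d_t = spec.d_t_vector
    dt = spec.frame_interval

    pos = gen_boltzmann_positions(spec.potential, P, spec.box, rng)
    positions = np.empty((F, P, 3))
    positions[0] = pos
    noise_scale = np.sqrt(2.0 * d_t * dt)
    for f in range(1, F):
        drift = -d_t * spec.potential.gradient(pos) * dt if spec.potential else 0.0
        pos = pos + drift + rng.normal(size=(P, 3)) * noise_scale
        positions[f] = pos

    mats = _propagate_orientations(spec, rng, P)
    body = topo.body_sites()
    sites = np.einsum("fpij,sj->fpsi", mats, body)
    coords = positions[:, :, None, :] + sites

    coords = coords.reshape(F, T, W, 3, 3).transpose(1, 0, 2, 3, 4)
    ensemble = TrajectoryEnsemble(
        topology=topo,
        coords=[np.ascontiguousarray(coords[t]) for t in range(T)],
        frame_interval=dt,
        box=np.asarray(spec.box, dtype=float),
        unwrapped=True,
    )
    return wrap_ensemble(ensemble) if wrapped else ensemble


def toy_tunnel_spec(
    n_trajectories: int = 100,
    n_frames: int = 200,
    n_waters: int = 20,
    seed: int = 0,
) -> SyntheticSpec:
    """Desk-scale analogue of a solvated macromolecular cavity.

    A soft-walled cylinder of radius 7.5 A runs along z through a
    30 x 30 x 60 A box up to a mouth at z = 40 A, beyond which lies an
    open bulk region used as the reference slab.  The rotational rate is
    chosen so the dipole is still partially correlated at the default
    50 ps lag (6 D_rot tau = 1.5), keeping the Q inversion in range.
    """
    box = (30.0, 30.0, 60.0)
    return SyntheticSpec(
        n_trajectories=n_trajectories,
        n_frames=n_frames,
        frame_interval=1.0,
        box=box,
        n_waters=n_waters,
        d_t=0.2,
        d_rot=0.005,
        potential=CylindricalTunnel(box=box, axis=2, radius=7.5, wall_k=2.0, mouth=40.0),
        orientation_mode="free",
        seed=seed,
    )
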