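import numpy as np
import pytest

import solvmap as sm


@pytest.fixture(scope="session")
def one_cell_grid():
    """A single huge cell: every finite position lands in cell (0,0,0)."""
    return sm.GridSpec(origin=(-5000.0, -5000.0, -5000.0), spacing=10000.0, dims=(1, 1, 1))


@pytest.fixture(scope="session")
def tip3p():
    return sm.WaterTopology(n_waters=1)


def make_ensemble(coords_list, frame_interval=1.0, box=(30.0, 30.0, 60.0),
                  unwrapped=True, topology=None):
    """Build an ensemble from raw per-trajectory site arrays."""
    coords_list = [np.asarray(c, dtype=float) for c in coords_list]
    n_waters = coords_list[0].shape[1]
    topo = topology or sm.WaterTopology(n_waters=n_waters)
    return sm.TrajectoryEnsemble(
        topology=topo, coords=coords_list, frame_interval=frame_interval,
        box=np.asarray(box, dtype=float), unwrapped=unwrapped,
    )


def water_at(origin, orientation=None, topology=None):
    """Site coordinates (3, 3) of one rigid water with its oxygen at `origin`."""
    topo = topology or sm.WaterTopology(n_waters=1)
    body = topo.body_sites()
    if orientation is not None:
        body = body @ np.asarray(orientation).T
    return np.asarray(origin, dtype=float) + body


def harmonic_expected_counts(k, center, box, grid, n):
    """Exact expected per-cell counts for n Boltzmann draws in a separable
    harmonic well truncated to the box: products of Gaussian cell integrals."""
    from scipy.special import erf

    probs = []
    for a in range(3):
        sig = 1.0 / np.sqrt(k[a])
        cdf = lambda x: 0.5 * (1.0 + erf((x - center[a]) / (sig * np.sqrt(2.0))))
        edges = grid.edges(a)
        probs.append(np.diff(cdf(edges)) / (cdf(box[a]) - cdf(0.0)))
    p = probs[0][:, None, None] * probs[1][None, :, None] * probs[2][None, None, :]
    return n * p, p


@pytest.fixture(scope="session")
def free_ensemble():
    """Small free-diffusion ensemble shared by estimator tests."""
    spec = sm.SyntheticSpec(n_trajectories=10, n_frames=120, frame_interval=1.0,
                            n_waters=5, d_t=0.2, d_rot=0.01, seed=42)
    return sm.gen_ensemble(spec)
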