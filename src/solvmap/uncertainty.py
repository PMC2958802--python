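"""Block averaging and bootstrap error maps for per-cell estimators.

The resampling unit is always a whole trajectory, never a frame: frames
within a trajectory are time-correlated, but the trajectories are
independent by construction, so trajectory-level blocks and resamples
give honest error bars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import ScalarField, SolvmapError, TrajectoryEnsemble

__all__ = ["ResamplingPlan", "block_average", "bootstrap_error"]

FieldEstimator = Callable[[TrajectoryEnsemble], ScalarField]


@dataclass(frozen=True)
class ResamplingPlan:
    """How to partition and resample the trajectory ensemble.

    Defaults: 50 blocks for block averaging; 100 bootstrap resamples of
    50 trajectories drawn with replacement.
    """

    n_blocks: int = 50
    n_boot: int = 100
    boot_sample_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError(f"n_blocks must be >= 2, got {self.n_blocks}")
        if self.n_boot < 2:
            raise ValueError(f"n_boot must be >= 2, got {self.n_boot}")
        if self.boot_sample_size < 1:
            raise ValueError("boot_sample_size must be >= 1")


def block_average(
    ensemble: TrajectoryEnsemble,
    estimator: FieldEstimator,
    plan: ResamplingPlan = ResamplingPlan(),
    require_all_blocks: bool = False,
) -> ScalarField:
    """Evaluate an estimator per block of trajectories and average the blocks.

    Blocks are contiguous runs of trajectory indices (the trajectories
    are independent, so any partition is valid).  Cells missing (masked)
    in some blocks are averaged over the available blocks by default, or
    masked entirely when ``require_all_blocks`` is set.
    """
    n = ensemble.n_trajectories
    if n < plan.n_blocks:
        raise SolvmapError(
            f"cannot form {plan.n_blocks} blocks from {n} trajectories"
        )
    chunks = np.array_split(np.arange(n), plan.n_blocks)
    template: ScalarField | None = None
    acc = None
    valid = None
    ns = None
    for chunk in chunks:
        f = estimator(ensemble.subset(list(chunk)))
        if template is None:
            template = f
            acc = np.zeros_like(f.values, dtype=float)
            valid = np.zeros(f.values.shape, dtype=np.int64)
            ns = np.zeros(f.values.shape, dtype=np.int64)
        acc += np.where(f.mask, np.nan_to_num(f.values), 0.0)
        valid += f.mask
        ns += f.n_samples
    assert template is not None
    if require_all_blocks:
        mask = valid == plan.n_blocks
    else:
        mask = valid > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = acc / valid
    out = ScalarField(template.grid, mean, ns, mask, template.units, dict(template.meta))
    out.meta.update(n_blocks=plan.n_blocks)
    return out


def bootstrap_error(
    ensemble: TrajectoryEnsemble,
    estimator: FieldEstimator,
    plan: ResamplingPlan = ResamplingPlan(),
) -> ScalarField:
    """Per-cell standard deviation of an estimator across bootstrap resamples.

    Each resample draws ``boot_sample_size`` whole trajectories with
    replacement; the error map is the per-cell sd (ddof=1) over resamples
    in which the cell was unmasked.  Deterministic under a fixed seed.
    """
    n = ensemble.n_trajectories
    if n < 2:
        raise SolvmapError("bootstrap needs at least 2 trajectories")
    rng = np.random.default_rng(plan.seed)
    template: ScalarField | None = None
    s1 = s2 = None
    valid = None
    failures = 0
    for _ in range(plan.n_boot):
        idx = rng.integers(0, n, size=plan.boot_sample_size)
        try:
            f = estimator(ensemble.subset(idx.tolist()))
        except SolvmapError as exc:
            failures += 1
            warnings.warn(f"bootstrap resample failed and was skipped: {exc}",
                          stacklevel=2)
            continue
        if template is None:
            template = f
            s1 = np.zeros_like(f.values, dtype=float)
            s2 = np.zeros_like(f.values, dtype=float)
            valid = np.zeros(f.values.shape, dtype=np.int64)
        v = np.where(f.mask, np.nan_to_num(f.values), 0.0)
        s1 += v
        s2 += v * v
        valid += f.mask
    if failures > 0.1 * plan.n_boot or template is None:
        raise SolvmapError(
            f"{failures}/{plan.n_boot} bootstrap resamples failed; "
            "estimator is unstable under resampling"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = s1 / valid
        var = (s2 - valid * mean**2) / (valid - 1)
    err = np.sqrt(np.clip(var, 0.0, None))
    mask = valid >= 2
    out = ScalarField(template.grid, err, valid.astype(np.int64), mask,
                      template.units, {})
    out.meta.update(n_boot=plan.n_boot, boot_sample_size=plan.boot_sample_size,
                    seed=plan.seed, failed_resamples=failures)
    return out
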