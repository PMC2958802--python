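"""Population classification of solvent cells.

Two schemes label each grid cell by how bulk-like its water is:

* by rotational entropy — bound (S < 0.7 k_B, water frozen into one or
  two orientational states), bulk-like (S > 3.0 k_B, twenty or more
  accessible states out of 28), intermediate otherwise;
* by free energy — bulk-like when the PMF lies within one standard
  deviation of the bulk-slab value, otherwise favorable (below the band)
  or unfavorable (above it).

An entropy deficit dS maps to a fractional loss of effective accessible
states through exp(S): 100 * (1 - exp(-dS)) percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BulkReference, GridError, GridSpec, ScalarField

__all__ = [
    "PopulationThresholds",
    "LabelField",
    "classify_by_entropy",
    "classify_by_entropy_pmf",
    "orientational_freedom_reduction",
    "UNLABELED",
]

UNLABELED = -1

ENTROPY_LEGEND = {0: "bound", 1: "intermediate", 2: "bulk-like"}
PMF_LEGEND = {0: "favorable", 1: "bulk-like", 2: "unfavorable"}


@dataclass(frozen=True)
class PopulationThresholds:
    """Entropy cutoffs (k_B) and the PMF bulk-band width (in bulk sds)."""

    bound: float = 0.7
    bulk_like: float = 3.0
    bulk_band_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.bound >= self.bulk_like:
            raise ValueError(
                f"bound cutoff ({self.bound}) must be below bulk-like cutoff "
                f"({self.bulk_like})"
            )
        if self.bulk_band_sd <= 0:
            raise ValueError("bulk band width must be positive")


@dataclass
class LabelField:
    """Per-cell categorical labels with a legend; -1 marks unlabeled (masked) cells."""

    grid: GridSpec
    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        """Cells per label name (unlabeled cells under 'unlabeled')."""
        out = {name: int(np.sum(self.labels == code)) for code, name in self.legend.items()}
        out["unlabeled"] = int(np.sum(self.labels == UNLABELED))
        return out

    @property
    def n_labeled(self) -> int:
        return int(np.sum(self.labels != UNLABELED))


def classify_by_entropy(s: ScalarField, thr: PopulationThresholds = PopulationThresholds()) -> LabelField:
    """Bound / intermediate / bulk-like by rotational entropy.

    Strict inequalities: a cell exactly at a cutoff is intermediate.
    Masked cells stay unlabeled.
    """
    if s.units != "k_B":
        raise ValueError(f"expected an entropy field in k_B, got units {s.units!r}")
    labels = np.full(s.grid.dims, UNLABELED, dtype=np.int8)
    v = s.values
    labels[s.mask & (v < thr.bound)] = 0
    labels[s.mask & (v >= thr.bound) & (v <= thr.bulk_like)] = 1
    labels[s.mask & (v > thr.bulk_like)] = 2
    return LabelField(s.grid, labels, dict(ENTROPY_LEGEND))


def classify_by_entropy_pmf(
    s: ScalarField,
    w: ScalarField,
    bulk: BulkReference,
    thr: PopulationThresholds = PopulationThresholds(),
) -> LabelField:
    """Joint entropy-PMF population: free energy relative to the bulk band.

    Bulk-like where |W - W_bulk| <= bulk_band_sd * sd (sd = spatial spread
    of the bulk-slab cells); favorable below the band, unfavorable above.
    Cells masked in either input field stay unlabeled.
    """
    if s.grid != w.grid:
        raise GridError("entropy and PMF fields must share one grid")
    band = thr.bulk_band_sd * bulk.sd
    labels = np.full(w.grid.dims, UNLABELED, dtype=np.int8)
    ok = s.mask & w.mask
    dev = w.values - bulk.mean
    labels[ok & (np.abs(dev) <= band)] = 1
    labels[ok & (dev > band)] = 2
    labels[ok & (dev < -band)] = 0
    return LabelField(w.grid, labels, dict(PMF_LEGEND))


def orientational_freedom_reduction(entropy_deficit: float) -> float:
    """Percent loss of effective accessible orientational states.

    The effective state count behind an entropy S is exp(S); a deficit
    dS relative to bulk therefore removes 100 * (1 - exp(-dS)) percent
    of the states (e.g. dS = 0.3 k_B -> ~26%).
    """
    return 100.0 * (1.0 - np.exp(-float(entropy_deficit)))
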