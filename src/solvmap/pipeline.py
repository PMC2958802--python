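"""Configuration-driven end-to-end analysis.

A single declarative config (YAML or dict) names the input trajectories,
grid, bulk slab, lag, thresholds and resampling plan; ``run_pipeline``
then computes every map — occupancy, PMF, rotational entropy, dipole
fluctuation tensor with its summaries and components, translational
diffusion (total and per axis), rotational decorrelation and diffusion,
bootstrap error maps and population labels — and writes them as
delimited text grids plus a machine-readable summary.  Reruns with the
same config and seed reproduce the summary byte for byte.

Thermodynamic fields are computed on the coordinates as loaded (wrapped
input stays in the box, which is what a density histogram needs); the
kinetic stage unwraps first, since squared displacements across a
periodic boundary are meaningless.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .classify import (
    LabelField,
    PopulationThresholds,
    classify_by_entropy,
    classify_by_entropy_pmf,
)
from .core import (
    BulkReference,
    FieldSlice,
    GridSpec,
    ScalarField,
    Slab,
    SolvmapError,
    TrajectoryEnsemble,
    WaterTopology,
    axis_number,
    extract_slice,
    unwrap,
)
from .io import load_trajectories, write_field, write_slice_matrix
from .kinetics import (
    LagSpec,
    rotational_decorrelation_field,
    rotational_diffusion_field,
    translational_diffusion_field,
)
from .thermo import (
    DEFAULT_MIN_SAMPLES,
    bulk_reference,
    count_field,
    dipole_fluctuation_tensor_field,
    offdiagonal_sum_field,
    pmf_field,
    rotational_entropy_field,
    tensor_trace_field,
)
from .uncertainty import ResamplingPlan, bootstrap_error

__all__ = ["RunConfig", "run_pipeline", "export_slice_map", "write_label_field"]

_TENSOR_COMPONENTS = [(0, 0, "xx"), (1, 1, "yy"), (2, 2, "zz"),
                      (0, 1, "xy"), (0, 2, "xz"), (1, 2, "yz")]


@dataclass
class RunConfig:
    """Validated analysis configuration."""

    paths: list[str]
    format: str
    topology: WaterTopology
    grid: GridSpec
    bulk_slab: Slab
    output_dir: str
    frame_interval: float | None = None
    input_unwrapped: bool = False
    lag: LagSpec = dc_field(default_factory=LagSpec)
    min_samples: int = DEFAULT_MIN_SAMPLES
    thresholds: PopulationThresholds = dc_field(default_factory=PopulationThresholds)
    resampling: ResamplingPlan = dc_field(default_factory=ResamplingPlan)
    error_fields: tuple[str, ...] = ("pmf", "rotational_entropy")
    slices: list[dict] = dc_field(default_factory=list)

    @classmethod
    def from_dict(cls, cfg: dict[str, Any], base_dir: str | os.PathLike = ".") -> "RunConfig":
        base = Path(base_dir)
        try:
            inp = cfg["input"]
            paths = [str(base / p) for p in inp["paths"]]
        except KeyError as exc:
            raise SolvmapError(f"config missing required key: {exc}") from exc
        if not paths:
            raise SolvmapError("config lists no trajectory files")
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise SolvmapError(f"trajectory files not found: {missing}")
        topo_cfg = cfg.get("topology", {})
        topology = WaterTopology(
            n_waters=int(topo_cfg.get("n_waters", cfg.get("n_waters", 1))),
            charges=tuple(topo_cfg.get("charges", (-0.834, 0.417, 0.417))),
            oh_length=float(topo_cfg.get("oh_length", 0.9572)),
            hoh_angle=float(topo_cfg.get("hoh_angle", 104.52)),
        )
        g = cfg.get("grid", {})
        if "dims" in g:
            grid = GridSpec(
                origin=tuple(g.get("origin", (0.0, 0.0, 0.0))),
                spacing=float(g.get("spacing", 1.0)),
                dims=tuple(g["dims"]),
            )
        elif "box" in g:
            grid = GridSpec.from_box(g["box"], spacing=float(g.get("spacing", 1.0)),
                                     origin=g.get("origin", (0.0, 0.0, 0.0)))
        else:
            raise SolvmapError("config grid needs either dims or box")
        b = cfg["bulk"]
        slab = Slab(axis=b.get("axis", "z"), lo=float(b["lo"]), hi=float(b["hi"]))
        thr_cfg = cfg.get("thresholds", {})
        thresholds = PopulationThresholds(
            bound=float(thr_cfg.get("bound", 0.7)),
            bulk_like=float(thr_cfg.get("bulk_like", 3.0)),
            bulk_band_sd=float(thr_cfg.get("bulk_band_sd", 1.0)),
        )
        rs = cfg.get("resampling", {})
        plan = ResamplingPlan(
            n_blocks=int(rs.get("n_blocks", 50)),
            n_boot=int(rs.get("n_boot", 100)),
            boot_sample_size=int(rs.get("sample_size", 50)),
            seed=int(rs.get("seed", 0)),
        )
        return cls(
            paths=paths,
            format=str(inp.get("format", "fixture")),
            topology=topology,
            grid=grid,
            bulk_slab=slab,
            output_dir=str(base / cfg.get("output", {}).get("dir", "solvmap_out")),
            frame_interval=inp.get("frame_interval"),
            input_unwrapped=bool(inp.get("unwrapped", False)),
            lag=LagSpec(float(cfg.get("lag", {}).get("ps", 50.0))),
            min_samples=int(cfg.get("min_samples", DEFAULT_MIN_SAMPLES)),
            thresholds=thresholds,
            resampling=plan,
            error_fields=tuple(cfg.get("error_fields", ("pmf", "rotational_entropy"))),
            slices=list(cfg.get("slices", [])),
        )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls.from_dict(cfg, base_dir=path.parent)


def write_label_field(path: str | os.PathLike, labels: LabelField, name: str) -> None:
    """Export a label map: legend in the header, one ``i j k label`` row per cell."""
    g = labels.grid
    with open(path, "w") as fh:
        fh.write(f"# solvmap-labels name={name}\n")
        fh.write(
            f"# grid origin={g.origin[0]:g},{g.origin[1]:g},{g.origin[2]:g} "
            f"spacing={g.spacing:g} dims={g.dims[0]},{g.dims[1]},{g.dims[2]}\n"
        )
        legend = " ".join(f"{code}={nm}" for code, nm in sorted(labels.legend.items()))
        fh.write(f"# legend -1=unlabeled {legend}\n")
        idx = np.indices(g.dims).reshape(3, -1).T
        for (i, j, k), lab in zip(idx, labels.labels.ravel()):
            fh.write(f"{i} {j} {k} {int(lab)}\n")


def export_slice_map(
    field: ScalarField,
    axis: int | str,
    coordinate: float,
    normalization: str = "absolute",
    bulk: BulkReference | None = None,
) -> FieldSlice:
    """Slice a field and optionally rescale to percent of the bulk value."""
    sl = extract_slice(field, axis, coordinate)
    if normalization == "percent_of_bulk":
        if bulk is None:
            raise SolvmapError("percent_of_bulk normalization needs a bulk reference")
        if bulk.mean == 0:
            raise SolvmapError("bulk mean is zero; cannot normalize")
        sl.values = 100.0 * sl.values / bulk.mean
        sl.units = "% of bulk"
    elif normalization != "absolute":
        raise SolvmapError(f"unknown normalization {normalization!r}")
    return sl


def _bulk_stats(field: ScalarField, slab: Slab) -> dict[str, float] | None:
    try:
        ref = bulk_reference(field, slab)
    except SolvmapError:
        return None
    return {"mean": round(float(ref.mean), 10), "sd": round(float(ref.sd), 10),
            "n_cells": ref.n_cells}


def run_pipeline(config: RunConfig, ensemble: TrajectoryEnsemble | None = None) -> dict:
    """Run every estimator and write all outputs; returns the summary dict.

    Stages: load -> histogram/PMF -> rotational entropy -> dipole tensor
    -> kinetics (on unwrapped coordinates) -> bootstrap errors ->
    classification -> slices -> summary.  Any stage error aborts with
    the stage named; files written before the failure are flagged as
    partial in the run log.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"solvmap {__version__}"]
    written: list[str] = []

    def _write(name: str, field: ScalarField) -> None:
        write_field(out_dir / f"{name}.dat", field, name=name)
        written.append(f"{name}.dat")

    stage = "load"
    try:
        if ensemble is None:
            ensemble = load_trajectories(
                config.paths, config.topology, format=config.format,
                frame_interval=config.frame_interval,
                unwrapped=config.input_unwrapped,
            )
        log_lines.append(
            f"loaded {ensemble.n_trajectories} trajectories, "
            f"{sum(ensemble.n_frames)} frames, {ensemble.topology.n_waters} waters"
        )
        grid = config.grid
        ms = config.min_samples

        stage = "histogram/pmf"
        counts = count_field(ensemble, grid)
        _write("counts", counts)
        count_bulk = bulk_reference(counts, config.bulk_slab, min_samples=ms)
        pmf = pmf_field(counts, count_bulk, min_samples=ms)
        _write("pmf", pmf)

        stage = "rotational entropy"
        entropy = rotational_entropy_field(ensemble, grid, min_samples=ms)
        _write("rotational_entropy", entropy)

        stage = "dipole tensor"
        tensor = dipole_fluctuation_tensor_field(ensemble, grid, min_samples=ms)
        trace = tensor_trace_field(tensor)
        offdiag = offdiagonal_sum_field(tensor)
        _write("tensor_trace", trace)
        _write("offdiagonal_sum", offdiag)
        for a, b, nm in _TENSOR_COMPONENTS:
            comp = ScalarField(grid, tensor.values[..., a, b].copy(),
                               tensor.n_samples.copy(), tensor.mask.copy(),
                               units="Debye^2")
            _write(f"tensor_{nm}", comp)

        stage = "kinetics"
        kinetic_ens = unwrap(ensemble)
        trans = translational_diffusion_field(kinetic_ens, grid, config.lag, min_samples=ms)
        _write("diffusion", trans.total)
        for a, nm in zip(range(3), "xyz"):
            _write(f"diffusion_{nm}", trans.per_axis[a])
        _write("msd", trans.msd)
        q = rotational_decorrelation_field(kinetic_ens, grid, config.lag, min_samples=ms)
        _write("rotational_q", q)
        d_rot = rotational_diffusion_field(q, config.lag)
        _write("rotational_diffusion", d_rot)

        stage = "bootstrap errors"
        n_traj = ensemble.n_trajectories
        plan = config.resampling
        # resamples hold boot_sample_size trajectories, not n_traj: scale the
        # per-cell sample floor so cells well-sampled in the full data are
        # not masked out of every resample
        ms_rs = max(1, int(ms * min(1.0, plan.boot_sample_size / n_traj)))

        def _pmf_estimator(e: TrajectoryEnsemble) -> ScalarField:
            c = count_field(e, grid)
            return pmf_field(c, bulk_reference(c, config.bulk_slab, min_samples=ms_rs),
                             min_samples=ms_rs)

        error_specs = {
            "pmf": _pmf_estimator,
            "rotational_entropy": lambda e: rotational_entropy_field(
                e, grid, min_samples=ms_rs),
        }
        if plan.boot_sample_size > 0 and n_traj >= 2:
            for name in config.error_fields:
                if name not in error_specs:
                    raise SolvmapError(f"no bootstrap support for field {name!r}")
                err = bootstrap_error(ensemble, error_specs[name], plan)
                _write(f"{name}_err", err)
        else:
            log_lines.append("bootstrap skipped: fewer than 2 trajectories")

        stage = "classification"
        labels_entropy = classify_by_entropy(entropy, config.thresholds)
        write_label_field(out_dir / "labels_entropy.dat", labels_entropy, "labels_entropy")
        written.append("labels_entropy.dat")
        pmf_bulk = _bulk_stats(pmf, config.bulk_slab)
        labels_pmf = None
        if pmf_bulk is not None:
            bulk_ref_pmf = bulk_reference(pmf, config.bulk_slab)
            labels_pmf = classify_by_entropy_pmf(entropy, pmf, bulk_ref_pmf,
                                                 config.thresholds)
            write_label_field(out_dir / "labels_pmf.dat", labels_pmf, "labels_pmf")
            written.append("labels_pmf.dat")

        stage = "slices"
        named_fields = {
            "counts": counts, "pmf": pmf, "rotational_entropy": entropy,
            "tensor_trace": trace, "offdiagonal_sum": offdiag,
            "diffusion": trans.total, "rotational_q": q,
            "rotational_diffusion": d_rot,
        }
        for req in config.slices:
            fname = req.get("field", "pmf")
            if fname not in named_fields:
                raise SolvmapError(f"cannot slice unknown field {fname!r}")
            f = named_fields[fname]
            norm = req.get("normalization", "absolute")
            bulk = None
            if norm == "percent_of_bulk":
                bulk = bulk_reference(f, config.bulk_slab)
            sl = export_slice_map(f, req["axis"], float(req["coord"]), norm, bulk)
            out_name = f"slice_{fname}_{req['axis']}_{float(req['coord']):g}.dat"
            write_slice_matrix(out_dir / out_name, sl,
                               header=f"{fname} axis={req['axis']} coord={req['coord']} "
                                      f"units={sl.units}")
            written.append(out_name)

        stage = "summary"
        summary: dict[str, Any] = {
            "version": __version__,
            "seed": plan.seed,
            "n_trajectories": ensemble.n_trajectories,
            "total_observations": ensemble.total_observations,
            "out_of_grid": counts.meta.get("out_of_grid", 0),
            "bulk": {
                name: _bulk_stats(f, config.bulk_slab)
                for name, f in named_fields.items()
            },
            "masked_cells": {
                name: int((~f.mask).sum()) for name, f in named_fields.items()
            },
            "label_counts": {
                "entropy": labels_entropy.counts(),
                **({"pmf": labels_pmf.counts()} if labels_pmf is not None else {}),
            },
            "files": sorted(written),
        }
        with open(out_dir / "summary.yaml", "w") as fh:
            yaml.safe_dump(summary, fh, sort_keys=True)
        log_lines.append("pipeline complete")
    except Exception as exc:
        log_lines.append(f"FAILED at stage '{stage}': {exc}")
        if written:
            log_lines.append(f"partial outputs: {sorted(written)}")
        with open(out_dir / "run.log", "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
        raise SolvmapError(f"pipeline failed at stage '{stage}': {exc}") from exc

    with open(out_dir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return summary
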