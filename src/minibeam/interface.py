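"""Configuration, experiment runner and command-line interface.

A single structured YAML file describes one experiment (``scan``,
``benchmark``, ``calibrate``, ``dose`` or ``synth``) together with the
nozzle, source and stage-specific blocks.  Every result file records the
seed, a hash of the resolved configuration and the package version, so any
output can be regenerated from its own provenance block.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import metadata, resources
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from .beam_source import BeamSource, make_source
from .benchmark_calibration import (
    MeasuredSizeTable,
    ParametrisationGrid,
    calibrate_source,
    feasibility_map,
)
from .dose_engine import GridLayout, PhantomSpec, analyze_dose, compute_dose_grid
from .metrics import is_minibeam
from .optimizer import (
    QuadScanSpec,
    default_field_grid,
    estimate_uncertainty,
    scan_quadrupoles,
    select_minimum,
)
from .synthetic_data import SyntheticSpec, gen_measured_sizes
from .transport import NozzleConfig, build_nozzle

__all__ = ["RunConfig", "load_config", "run_experiment", "cli"]

log = logging.getLogger("minibeam")

_EXPERIMENTS = ("scan", "benchmark", "calibrate", "dose", "synth")

_SCHEMA: dict[str, set[str]] = {
    "": {"experiment", "seed", "output_dir", "verbosity", "nozzle", "source",
         "scan", "benchmark", "calibrate", "dose", "synth"},
    "nozzle": {"preset", "air_gap_cm", "target_offset_cm", "focal_length_cm",
               "quad_length_cm", "aperture_cm"},
    "source": {"energy_MeV", "energy_spread", "sigma_x_mm", "sigma_y_mm",
               "div_x_mrad", "div_y_mrad", "r_xx", "r_yy"},
    "scan": {"step_T", "n_particles", "refine_fraction", "n_energy_nodes"},
    "benchmark": {"grid", "plane"},
    "calibrate": {"measured_csv", "source_sigmas"},
    "dose": {"spacing_mm", "n_beams", "mode", "n_primaries", "repeats",
             "quad_fields", "arrangement", "phantom"},
    "synth": {"noise_rel"},
}


@dataclass
class RunConfig:
    """Validated experiment configuration."""

    experiment: str
    seed: int
    output_dir: str = "results"
    verbosity: str = "info"
    nozzle: dict = field(default_factory=dict)
    source: dict | None = None
    scan: dict = field(default_factory=dict)
    benchmark: dict = field(default_factory=dict)
    calibrate: dict = field(default_factory=dict)
    dose: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in _EXPERIMENTS:
            raise ValueError(f"experiment must be one of {_EXPERIMENTS}")
        if self.experiment in ("scan", "dose") and not self.source:
            raise ValueError(f"experiment {self.experiment!r} requires a source block")
        if self.experiment == "calibrate" and "measured_csv" not in self.calibrate:
            raise ValueError("calibrate requires calibrate.measured_csv")

    def build_nozzle(self) -> NozzleConfig:
        return build_nozzle(
            self.nozzle.get("preset", "optimized"),
            air_gap_cm=float(self.nozzle.get("air_gap_cm", 10.0)),
            target_offset_cm=float(self.nozzle.get("target_offset_cm", 0.0)),
            focal_length_cm=float(self.nozzle.get("focal_length_cm", 100.0)),
            quad_length_cm=float(self.nozzle.get("quad_length_cm", 30.0)),
            aperture_cm=float(self.nozzle.get("aperture_cm", 5.0)),
        )

    def build_source(self) -> BeamSource:
        s = self.source or {}
        return make_source(
            energy=float(s["energy_MeV"]),
            energy_spread=float(s.get("energy_spread", 0.01)),
            sigma_x=float(s["sigma_x_mm"]),
            sigma_y=float(s["sigma_y_mm"]),
            div_x=float(s["div_x_mrad"]),
            div_y=float(s["div_y_mrad"]),
            r_xx=float(s["r_xx"]),
            r_yy=float(s["r_yy"]),
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _check_keys(block: dict, name: str) -> None:
    allowed = _SCHEMA[name]
    for key in block:
        if key not in allowed:
            raise ValueError(
                f"unknown key {key!r} in config block {name or '<root>'!r}; "
                f"allowed: {sorted(allowed)}"
            )


def load_config(path) -> RunConfig:
    """Load and validate a YAML experiment configuration.

    Unknown keys are rejected with the offending key and block named.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _check_keys(raw, "")
    for block in ("nozzle", "source", "scan", "benchmark", "calibrate", "dose", "synth"):
        if block in raw and raw[block] is not None:
            if not isinstance(raw[block], dict):
                raise ValueError(f"config block {block!r} must be a mapping")
            _check_keys(raw[block], block)
    if "nozzle" in raw and raw["nozzle"] and float(raw["nozzle"].get("air_gap_cm", 0)) < 0:
        raise ValueError("nozzle.air_gap_cm must be >= 0")
    if "experiment" not in raw or "seed" not in raw:
        raise ValueError("config requires 'experiment' and 'seed'")
    return RunConfig(**{k: v for k, v in raw.items() if v is not None})


def packaged_config(name: str) -> RunConfig:
    """Load one of the bundled example configurations by stem name."""
    ref = resources.files("minibeam").joinpath(f"configs/{name}.yaml")
    with resources.as_file(ref) as p:
        return load_config(p)


def _provenance(config: RunConfig) -> dict:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    try:
        version = metadata.version("minibeam")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "package_version": version,
    }


def _scan_spec(config: RunConfig, nozzle: NozzleConfig) -> QuadScanSpec:
    blk = config.scan
    step = float(blk.get("step_T", 0.04))
    fields = tuple(
        default_field_grid(nozzle.elements[i].max_field_T, step)
        for i in nozzle.scannable_quads()
    )
    return QuadScanSpec(
        field_values=fields,
        n_particles=int(blk.get("n_particles", 100_000)),
        refine_fraction=float(blk.get("refine_fraction", 0.01)),
        n_energy_nodes=int(blk.get("n_energy_nodes", 5)),
        base_seed=int(config.seed),
    )


def run_experiment(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Run the configured experiment; write result files; return the summary."""
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    summary: dict = {"experiment": config.experiment, "provenance": _provenance(config)}
    try:
        if config.experiment == "scan":
            nozzle = config.build_nozzle()
            source = config.build_source()
            result = scan_quadrupoles(nozzle, source, _scan_spec(config, nozzle))
            cfg, h, v = select_minimum(result)
            unc = estimate_uncertainty(result)
            result.table.to_csv(out / "scan_grid.csv", index=False)
            summary.update(
                {
                    "argmin": cfg,
                    "h_fwhm_mm": h,
                    "v_fwhm_mm": v,
                    "h_uncertainty_mm": list(unc.h),
                    "v_uncertainty_mm": list(unc.v),
                    "is_minibeam": bool(h <= 1.0 and v <= 1.0),
                }
            )
        elif config.experiment == "benchmark":
            nozzle = config.build_nozzle()
            energy = float((config.source or {}).get("energy_MeV", 100.0))
            grid = (
                ParametrisationGrid.small()
                if config.benchmark.get("grid", "small") == "small"
                else ParametrisationGrid()
            )
            spec = _scan_spec(config, nozzle)
            maps = feasibility_map(nozzle, energy, grid, spec)
            feasible = {}
            for plane, fmap in maps.items():
                fmap.to_frame().to_csv(out / f"feasibility_{plane}.csv")
                feasible[plane] = int(fmap.minibeam_mask.sum())
            summary.update({"n_parametrisations": grid.count, "feasible_cells": feasible})
        elif config.experiment == "calibrate":
            nozzle = config.build_nozzle()
            measured = MeasuredSizeTable.from_csv(config.calibrate["measured_csv"])
            sigmas = {
                float(k): tuple(v) for k, v in config.calibrate["source_sigmas"].items()
            }
            res = calibrate_source(measured, nozzle, ParametrisationGrid.small(), sigmas)
            summary["calibration"] = {
                str(e): {
                    "div_x_mrad": r.source.div_x,
                    "div_y_mrad": r.source.div_y,
                    "r_xx": r.source.r_xx,
                    "r_yy": r.source.r_yy,
                    "mean_rel_dev_x_pct": r.mean_rel_dev_x_pct,
                    "mean_rel_dev_y_pct": r.mean_rel_dev_y_pct,
                }
                for e, r in res.items()
            }
        elif config.experiment == "dose":
            nozzle = config.build_nozzle()
            source = config.build_source()
            blk = config.dose
            phantom_blk = blk.get("phantom", {})
            phantom = PhantomSpec(
                width_cm=float(phantom_blk.get("width_cm", 2.0)),
                height_cm=float(phantom_blk.get("height_cm", 2.0)),
                depth_cm=float(phantom_blk.get("depth_cm", 10.0)),
                voxel_mm=tuple(phantom_blk.get("voxel_mm", (0.05, 0.05, 1.0))),
            )
            quad_fields = blk.get("quad_fields")
            arrangement = int(blk.get("arrangement", 0))
            if quad_fields is None:
                scan = scan_quadrupoles(nozzle, source, _scan_spec(config, nozzle))
                cfg, _, _ = select_minimum(scan)
                quad_fields = (cfg["B1"], cfg["B2"])
                arrangement = cfg["arrangement"]
            layout = GridLayout.from_nozzle(
                nozzle, float(blk.get("spacing_mm", 2.9)), int(blk.get("n_beams", 5))
            )
            grid = compute_dose_grid(
                nozzle, source, layout, phantom,
                mode=blk.get("mode", "analytic"),
                n=int(blk.get("n_primaries", 100_000)),
                repeats=int(blk.get("repeats", 50)),
                seed=config.seed,
                quad_fields=tuple(float(b) for b in quad_fields),
                arrangement=arrangement,
            )
            single = GridLayout(
                n=1, spacing_mm=layout.spacing_mm,
                offsets_mm=np.zeros((1, 2)), angles_mrad=np.zeros((1, 2)),
            )
            sgrid = compute_dose_grid(
                nozzle, source, single, phantom,
                mode="analytic", n=int(blk.get("n_primaries", 100_000)),
                repeats=1, seed=config.seed,
                quad_fields=tuple(float(b) for b in quad_fields),
                arrangement=arrangement,
            )
            ana = analyze_dose(grid, layout, single_beam_grid=sgrid)
            pd.DataFrame(
                {
                    "z_mm": ana.z_mm,
                    "pvdr": ana.pvdr,
                    "fwhm_mm": ana.fwhm_mm,
                    "peak_dose": ana.peak_dose,
                    "valley_dose": ana.valley_dose,
                }
            ).to_csv(out / "dose_profiles.csv", index=False)
            np.savez_compressed(
                out / "dose_grid.npz", dose=grid.dose,
                voxel_mm=np.array(phantom.voxel_mm),
            )
            (out / "dose_grid.json").write_text(
                json.dumps({"shape": list(grid.dose.shape),
                            "voxel_mm": list(phantom.voxel_mm), "units": "a.u."})
            )
            summary.update(
                {
                    "quad_fields_T": list(quad_fields),
                    "arrangement": arrangement,
                    "entrance_pvdr": float(ana.pvdr[0]),
                    "peak_to_entrance": ana.peak_to_entrance,
                    "bragg_depth_mm": ana.bragg_depth_mm,
                }
            )
        elif config.experiment == "synth":
            nozzle = config.build_nozzle()
            spec = SyntheticSpec(
                seed=config.seed, noise_rel=float(config.synth.get("noise_rel", 0.01))
            )
            table = gen_measured_sizes(spec, nozzle)
            table.to_csv(out / "measured_sizes.csv")
            summary["n_rows"] = len(table.data)
    except Exception as exc:
        raise RuntimeError(f"stage {config.experiment!r} failed: {exc}") from exc
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
def cli() -> None:
    """Magnetically focussed proton minibeam simulation pipeline."""


def _common(func):
    func = click.option("--config", "config_path", required=True, type=click.Path(exists=True))(func)
    func = click.option("--seed", type=int, default=None, help="override the config seed")(func)
    func = click.option("--out", "out_dir", type=click.Path(), default=None)(func)
    return func


def _run(experiment: str, config_path: str, seed: int | None, out_dir: str | None, **overrides):
    config = load_config(config_path)
    if config.experiment != experiment:
        raise click.UsageError(
            f"config is for experiment {config.experiment!r}, not {experiment!r}"
        )
    if seed is not None:
        config.seed = seed
    for block, values in overrides.items():
        getattr(config, block).update({k: v for k, v in values.items() if v is not None})
    summary = run_experiment(config, out_dir)
    click.echo(json.dumps(summary, indent=2, sort_keys=True))


@cli.command()
@_common
@click.option("--particles", type=int, default=None)
def scan(config_path, seed, out_dir, particles):
    """Quadrupole grid scan minimising the beam size at the target."""
    _run("scan", config_path, seed, out_dir, scan={"n_particles": particles})


@cli.command()
@_common
@click.option("--grid", type=click.Choice(["small", "full"]), default=None)
def benchmark(config_path, seed, out_dir, grid):
    """Source-parametrisation feasibility maps."""
    _run("benchmark", config_path, seed, out_dir, benchmark={"grid": grid})


@cli.command()
@_common
def calibrate(config_path, seed, out_dir):
    """Best-fit source parameters from a measured-size table."""
    _run("calibrate", config_path, seed, out_dir)


@cli.command()
@_common
@click.option("--mode", type=click.Choice(["analytic", "monte_carlo"]), default=None)
@click.option("--particles", type=int, default=None)
def dose(config_path, seed, out_dir, mode, particles):
    """Water-phantom minibeam-grid dose simulation."""
    _run("dose", config_path, seed, out_dir, dose={"mode": mode, "n_primaries": particles})


@cli.command()
@_common
def synth(config_path, seed, out_dir):
    """Generate a synthetic measured-size table."""
    _run("synth", config_path, seed, out_dir)
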