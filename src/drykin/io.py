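"""CSV I/O for drying runs, run configuration, and the analysis pipeline.

The run CSV schema is a plain table with a leading metadata block of
``# key: value`` comment lines::

    # method: CD
    # level: 40
    # dry_mass_g: 1.3
    # thickness_mm: 0.5
    time_min,mass_g
    0.0000,10.0000
    ...

Either a ``mass_g`` or a ``moisture_db`` column is accepted; dry-basis
files are converted back to masses through ``dry_mass_g``.  The reader
validates the physical invariants (monotone times starting at zero,
positive masses) and reports offending line numbers.

``run_pipeline`` ties the stages together — simulate or load runs, fit
and rank the model catalog, summarise drying rate and effective
diffusivity, optionally add energy and assay sections — and returns a
deterministic, JSON-serialisable report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .assays import anova_lsd_letters
from .energy import EnergyInput, energy_metrics
from .fitting import fit_catalog
from .models import model_names
from .simulate import ExperimentDesign, generate_drying_run, preset_design
from .transport import DryingRun, estimate_deff, mean_drying_rate, to_dry_basis

__all__ = [
    "read_run_csv",
    "write_run_csv",
    "RunConfig",
    "run_pipeline",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1


class RunCsvError(ValueError):
    """Malformed run CSV; the message names the offending line."""


def _parse_metadata(lines: list[str]) -> tuple[dict, int]:
    meta: dict[str, str] = {}
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            meta[key.strip()] = val.strip()
    return meta, i


def read_run_csv(path) -> DryingRun:
    """Read and validate a drying-run CSV (see module docstring)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise RunCsvError(f"{path}: empty file")
    meta, header_idx = _parse_metadata(lines)
    for key in ("method", "level", "dry_mass_g", "thickness_mm"):
        if key not in meta:
            raise RunCsvError(f"{path}: missing metadata line '# {key}: ...'")
    header = [c.strip() for c in lines[header_idx].split(",")]
    if "time_min" not in header:
        raise RunCsvError(f"{path}, line {header_idx + 1}: missing time_min column")
    if "mass_g" in header:
        value_col, dry_basis = "mass_g", False
    elif "moisture_db" in header:
        value_col, dry_basis = "moisture_db", True
    else:
        raise RunCsvError(
            f"{path}, line {header_idx + 1}: need a mass_g or moisture_db column"
        )
    it = header.index("time_min")
    iv = header.index(value_col)
    times, values = [], []
    for ln, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        if not line.strip():
            continue
        cells = line.split(",")
        try:
            tt = float(cells[it])
            vv = float(cells[iv])
        except (ValueError, IndexError):
            raise RunCsvError(f"{path}, line {ln}: non-numeric cell in {line!r}")
        if times and tt <= times[-1]:
            raise RunCsvError(
                f"{path}, line {ln}: time {tt} not greater than previous {times[-1]}"
            )
        times.append(tt)
        values.append(vv)
    dry_mass = float(meta["dry_mass_g"])
    masses = (np.array(values) if not dry_basis
              else dry_mass * (1.0 + np.array(values)))
    try:
        return DryingRun(
            times=np.array(times),
            masses=masses,
            dry_mass=dry_mass,
            method=meta["method"],
            level=float(meta["level"]),
            thickness=float(meta["thickness_mm"]) * 1e-3,
        )
    except ValueError as exc:
        raise RunCsvError(f"{path}: {exc}") from exc


def write_run_csv(run: DryingRun, path, dry_basis: bool = False) -> None:
    """Write a run in the canonical schema (times at 4 decimals)."""
    path = Path(path)
    lines = [
        f"# method: {run.method}",
        f"# level: {run.level:g}",
        f"# dry_mass_g: {run.dry_mass:g}",
        f"# thickness_mm: {run.thickness * 1e3:g}",
    ]
    if dry_basis:
        lines.append("time_min,moisture_db")
        m = (run.masses - run.dry_mass) / run.dry_mass
        for t, v in zip(run.times, m):
            lines.append(f"{t:.4f},{v:.6f}")
    else:
        lines.append("time_min,mass_g")
        for t, v in zip(run.times, run.masses):
            lines.append(f"{t:.4f},{v:.4f}")
    path.write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# pipeline

_CONFIG_KEYS = {
    "presets", "inputs", "models", "alpha", "deff_method",
    "noise_sd", "seed", "include_energy", "assays", "output",
}


@dataclass
class RunConfig:
    """Configuration of one pipeline invocation.

    Exactly one of ``presets`` (synthetic designs by name) or ``inputs``
    (run CSV paths) supplies the drying runs.  ``assays`` is an optional
    mapping analyte -> {condition -> replicate values}.
    """

    presets: list[str] = field(default_factory=list)
    inputs: list[str] = field(default_factory=list)
    models: list[str] | None = None
    alpha: float = 0.05
    deff_method: str = "slope"
    noise_sd: float | None = None
    seed: int = 0
    include_energy: bool = True
    assays: dict = field(default_factory=dict)
    output: str | None = None

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if bool(self.presets) == bool(self.inputs):
            raise ValueError("give exactly one of presets or inputs")
        if self.models is not None:
            if not self.models:
                raise ValueError("empty model subset")
            unknown = set(self.models) - set(model_names())
            if unknown:
                raise ValueError(f"unknown models: {sorted(unknown)}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        unknown = set(data) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _analyse_run(run: DryingRun, label: str, config: RunConfig,
                 design: ExperimentDesign | None = None) -> dict:
    series = to_dry_basis(run)
    table = fit_catalog(series.times, series.mr, models=config.models,
                        label=label, thickness=run.thickness)
    best = table.best()
    deff, deff_info = estimate_deff(series, run.thickness,
                                    method=config.deff_method)
    section = {
        "label": label,
        "method": run.method,
        "level": run.level,
        "n_obs": int(series.times.size),
        "duration_min": round(float(series.times[-1]), 4),
        "stopped": bool(run.stopped),
        "mean_drying_rate": mean_drying_rate(series),
        "deff_m2_per_s": deff,
        "deff_info": {k: v for k, v in deff_info.items() if k != "curve"},
        "selection": json.loads(table.to_json()),
        "best_model": best.as_dict(),
    }
    if config.include_energy and design is not None:
        energy_kwh = design.energy_kwh(float(series.times[-1]))
        if energy_kwh > 0 and series.m0 > series.moisture_db[-1]:
            inp = EnergyInput(
                energy_kwh=energy_kwh,
                dry_solid_kg=run.dry_mass / 1000.0,
                x_initial=series.m0,
                x_final=float(series.moisture_db[-1]),
            )
            res = energy_metrics(inp)
            section["energy"] = {
                "energy_kwh": energy_kwh,
                "sece": res.sece,
                "ee_percent": res.ee_percent,
                "identity_product": res.identity_product,
            }
    return section


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate/load -> fit -> transport metrics -> optional extras.

    Deterministic for a fixed config (the seed is recorded in the
    report).  Stage errors propagate with the run label attached.
    """
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "runs": [],
    }
    jobs: list[tuple[str, DryingRun, ExperimentDesign | None]] = []
    for i, name in enumerate(config.presets):
        design = preset_design(name)
        if config.noise_sd is not None:
            from dataclasses import replace
            design = replace(design, noise_sd=config.noise_sd)
        run = generate_drying_run(design, seed=config.seed + i)
        jobs.append((name, run, design))
    for path in config.inputs:
        jobs.append((str(path), read_run_csv(path), None))

    for label, run, design in jobs:
        try:
            report["runs"].append(_analyse_run(run, label, config, design))
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed for run {label!r}: {exc}"
                               ) from exc

    if config.assays:
        assay_section = {}
        for analyte, groups in config.assays.items():
            table = anova_lsd_letters(groups, alpha=config.alpha)
            assay_section[analyte] = {
                "f_statistic": table.f_statistic,
                "p_value": table.p_value,
                "means": table.means,
                "sds": table.sds,
                "letters": table.letters,
            }
        report["assays"] = assay_section

    if config.output:
        Path(config.output).write_text(json.dumps(report, indent=2))
    return report
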