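"""Configuration-driven orchestration of the full analysis battery.

A single YAML/JSON config names the systems (structure + replica
trajectories + optional parameter table), the reference system, and the
analysis settings (equilibration discard, dissociation threshold, width
metrics, entropy selections, force-analysis selections).  ``run_pipeline``
produces, per system, the per-residue dissociation table, groove widths,
RMSF, configurational entropy and residue-pair force matrix, with the
replica-exclusion rule applied before any averaging; ``compare_systems``
builds the difference tables against the reference.

Outputs are a pure function of (config, input files, seed); every table
is stamped with the config hash, seed and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .entropy import (
    entropy_convergence_error,
    positional_covariance,
    schlitter_entropy,
)
from .groove import WidthMetricSpec, groove_width_report
from .io import read_parameter_table, read_structure, read_trajectory
from .model import GrooveDynError, Selection, Topology, Trajectory
from .pairforce import (
    ForceModelParams,
    force_difference_map,
    interface_force_summary,
    residue_force_matrix,
)
from .select import select
from .superpose import (
    dissociation_profile,
    fit_trajectory,
    flag_full_dissociation,
    residue_rmsd_series,
    rmsf,
)

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "compare_systems"]

log = logging.getLogger("groovedyn.pipeline")


class ConfigError(GrooveDynError):
    """Invalid pipeline configuration; message names the config path."""


@dataclass
class SystemSpec:
    structure: str
    trajectories: list[str]
    parameters: str | None = None


@dataclass
class PipelineConfig:
    systems: dict[str, SystemSpec]
    reference_system: str
    fit_query: str
    measure_query: str
    rmsf_query: str
    n_terminal_label: str
    c_terminal_label: str
    equilibration_ns: float = 10.0
    dissociation_threshold_A: float = 3.0
    persistence_ns: float = 10.0
    width_metrics: list[dict] = field(default_factory=list)
    entropy_selections: dict[str, str] = field(default_factory=dict)
    temperature_K: float = 300.0
    entropy_drop_fraction: float = 0.10
    fda_selection_a: str | None = None
    fda_selection_b: str | None = None
    fda_floor_pN: float = 30.0
    fda_cutoff_A: float = 10.0
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def need(key: str) -> Any:
            if key not in raw:
                raise ConfigError(f"missing config key: {key}")
            return raw[key]

        systems_raw = need("systems")
        if not isinstance(systems_raw, dict) or not systems_raw:
            raise ConfigError("systems: must be a non-empty mapping")
        systems = {}
        for name, sys_raw in systems_raw.items():
            for k in ("structure", "trajectories"):
                if k not in sys_raw:
                    raise ConfigError(f"systems.{name}.{k}: missing")
            systems[name] = SystemSpec(
                structure=sys_raw["structure"],
                trajectories=list(sys_raw["trajectories"]),
                parameters=sys_raw.get("parameters"),
            )
        ref = need("reference_system")
        if ref not in systems:
            raise ConfigError(
                f"reference_system: {ref!r} is not among systems {sorted(systems)}"
            )
        kwargs = {
            k: raw[k]
            for k in (
                "equilibration_ns", "dissociation_threshold_A", "persistence_ns",
                "width_metrics", "entropy_selections", "temperature_K",
                "entropy_drop_fraction", "fda_selection_a", "fda_selection_b",
                "fda_floor_pN", "fda_cutoff_A", "seed",
            )
            if k in raw
        }
        return cls(
            systems=systems,
            reference_system=ref,
            fit_query=need("fit_query"),
            measure_query=need("measure_query"),
            rmsf_query=raw.get("rmsf_query", need("measure_query")),
            n_terminal_label=need("n_terminal_label"),
            c_terminal_label=need("c_terminal_label"),
            **kwargs,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        return cls.from_dict(raw)

    def digest(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _provenance(config: PipelineConfig) -> dict:
    return {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
    }


def _width_specs(config: PipelineConfig) -> list[WidthMetricSpec]:
    specs = []
    for m in config.width_metrics:
        specs.append(
            WidthMetricSpec(
                name=m["name"],
                atom_a=(m["atom_a"][0], int(m["atom_a"][1]), m["atom_a"][2]),
                atom_b=(m["atom_b"][0], int(m["atom_b"][1]), m["atom_b"][2]),
            )
        )
    return specs


def _concat(replicas: list[Trajectory], topology: Topology) -> Trajectory:
    coords = np.concatenate([t.coordinates for t in replicas], axis=0)
    # re-stamp times so they stay strictly increasing across replicas
    dt = np.median(np.diff(replicas[0].times)) if replicas[0].n_frames > 1 else 0.01
    times = dt * np.arange(1, coords.shape[0] + 1)
    return Trajectory(coordinates=coords, times=times, topology=topology)


def analyze_system(
    name: str, spec: SystemSpec, config: PipelineConfig
) -> dict[str, Any]:
    """Run the full analysis battery for one system; returns a report
    dict of DataFrames / plain dicts ready to be written."""
    missing = [p for p in [spec.structure, *spec.trajectories, spec.parameters]
               if p is not None and not Path(p).exists()]
    if missing:
        raise ConfigError(f"missing input files for system {name}: {missing}")
    topology, ref_frame = read_structure(spec.structure)
    if spec.parameters:
        topology = topology.with_parameters(read_parameter_table(spec.parameters))
    fit_sel = select(topology, config.fit_query)
    measure_sel = select(topology, config.measure_query)
    rmsf_sel = select(topology, config.rmsf_query)

    replicas = [read_trajectory(p, topology) for p in spec.trajectories]
    replicas = [t.discard_equilibration(config.equilibration_ns) for t in replicas]
    fitted = [fit_trajectory(t, ref_frame, fit_sel) for t in replicas]

    series = []
    labels: list[str] = []
    excluded = []
    for i, t in enumerate(fitted):
        labels, s = residue_rmsd_series(t, ref_frame, measure_sel)
        fully_gone = flag_full_dissociation(
            s, t.times, labels, config.n_terminal_label, config.c_terminal_label,
            threshold=config.dissociation_threshold_A,
            persistence_ns=config.persistence_ns,
        )
        if fully_gone:
            excluded.append(i)
            log.warning(
                "system %s replica %d: full dissociation detected; "
                "excluded from all analyses", name, i,
            )
        else:
            series.append(s)
    retained = [t for i, t in enumerate(fitted) if i not in excluded]
    if not retained:
        raise GrooveDynError(f"system {name}: every replica was excluded")
    profile = dissociation_profile(series, labels, config.dissociation_threshold_A)

    pooled = _concat(retained, topology)
    _, rmsf_labels, per_res_rmsf = rmsf(pooled, rmsf_sel)
    residues = pd.DataFrame(
        {
            "label": profile.residue_labels,
            "mean_rmsd_A": profile.mean_rmsd,
            "bound_fraction": profile.bound_fraction,
        }
    )
    rmsf_table = pd.DataFrame({"label": rmsf_labels, "rmsf_A": per_res_rmsf})

    widths = None
    if config.width_metrics:
        widths = groove_width_report(
            retained, _width_specs(config), system=name, t_equil_ns=0.0
        )

    entropy_report = {}
    for domain, query in config.entropy_selections.items():
        dom_sel = select(topology, query)
        dom_fitted = fit_trajectory(pooled, ref_frame, dom_sel)
        masses = topology.masses(dom_sel.atom_indices)
        res = schlitter_entropy(
            positional_covariance(dom_fitted, dom_sel), masses, config.temperature_K
        )
        err = entropy_convergence_error(
            dom_fitted, dom_sel, masses, config.temperature_K,
            config.entropy_drop_fraction, seed=config.seed,
        )
        entropy_report[domain] = {
            "S_J_per_K_mol": res.S,
            "convergence_error_J_per_K_mol": err,
            "n_frames": res.n_frames,
            "n_atoms": res.n_atoms,
            "temperature_K": config.temperature_K,
        }

    force_table = None
    force_matrix = None
    if config.fda_selection_a and config.fda_selection_b:
        model = ForceModelParams(cutoff=config.fda_cutoff_A)
        sel_a = select(topology, config.fda_selection_a)
        sel_b = select(topology, config.fda_selection_b)
        force_matrix = residue_force_matrix(pooled, sel_a, sel_b, model)
        rows = []
        for i, la in enumerate(force_matrix.residue_labels_a):
            for j, lb in enumerate(force_matrix.residue_labels_b):
                rows.append(
                    {
                        "label_a": la,
                        "label_b": lb,
                        "magnitude_pN": force_matrix.magnitude[i, j],
                        "sign": int(force_matrix.sign[i, j]),
                        "mean_fx": force_matrix.mean_vector[i, j, 0],
                        "mean_fy": force_matrix.mean_vector[i, j, 1],
                        "mean_fz": force_matrix.mean_vector[i, j, 2],
                    }
                )
        force_table = pd.DataFrame(rows)

    return {
        "name": name,
        "residues": residues,
        "rmsf": rmsf_table,
        "widths": widths,
        "entropy": entropy_report,
        "forces": force_table,
        "force_matrix": force_matrix,
        "replicas": {
            "n_input": len(replicas),
            "n_retained": len(retained),
            "excluded": excluded,
            "frames_retained": int(pooled.n_frames),
        },
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, dict]:
    """Run every system and write the report bundle under ``outdir``.

    Per system: ``residues.csv``, ``rmsf.csv``, ``widths.csv``,
    ``entropy.json``, ``forces.csv`` and ``replicas.json``; a top-level
    ``run.json`` carries provenance (config hash, seed, version).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports = {}
    for name, spec in config.systems.items():
        log.info("analyzing system %s (%d replicas)", name, len(spec.trajectories))
        report = analyze_system(name, spec, config)
        reports[name] = report
        sysdir = outdir / name
        sysdir.mkdir(exist_ok=True)
        report["residues"].to_csv(sysdir / "residues.csv", index=False)
        report["rmsf"].to_csv(sysdir / "rmsf.csv", index=False)
        if report["widths"] is not None:
            report["widths"].to_csv(sysdir / "widths.csv", index=False)
        (sysdir / "entropy.json").write_text(
            json.dumps(report["entropy"], indent=2, sort_keys=True)
        )
        if report["forces"] is not None:
            report["forces"].to_csv(sysdir / "forces.csv", index=False)
        (sysdir / "replicas.json").write_text(
            json.dumps(report["replicas"], indent=2, sort_keys=True)
        )
    (outdir / "run.json").write_text(
        json.dumps(_provenance(config), indent=2, sort_keys=True)
    )
    ref = reports[config.reference_system]
    for name, report in reports.items():
        if name == config.reference_system:
            continue
        diff = compare_systems(report, ref, floor_pN=config.fda_floor_pN)
        diffdir = outdir / f"{name}_vs_{config.reference_system}"
        diffdir.mkdir(exist_ok=True)
        diff["delta_rmsf"].to_csv(diffdir / "delta_rmsf.csv", index=False)
        (diffdir / "delta_entropy.json").write_text(
            json.dumps(diff["delta_entropy"], indent=2, sort_keys=True)
        )
        if diff["delta_widths"] is not None:
            diff["delta_widths"].to_csv(diffdir / "delta_widths.csv", index=False)
        if diff["delta_forces"] is not None:
            pd.DataFrame(diff["delta_forces"]).to_csv(
                diffdir / "delta_forces.csv", index=False
            )
    return reports


def compare_systems(
    report_a: dict, report_b: dict, floor_pN: float = 30.0
) -> dict[str, Any]:
    """Difference tables (system minus reference): per-residue delta-RMSF
    with an absolute column, per-domain delta-S, a floored force
    difference map, and delta groove widths."""
    a_rmsf, b_rmsf = report_a["rmsf"], report_b["rmsf"]
    if list(a_rmsf["label"]) != list(b_rmsf["label"]):
        raise GrooveDynError("incompatible RMSF selections between reports")
    delta_rmsf = pd.DataFrame(
        {
            "label": a_rmsf["label"],
            "delta_rmsf_A": a_rmsf["rmsf_A"].to_numpy() - b_rmsf["rmsf_A"].to_numpy(),
            "abs_delta_rmsf_A": np.abs(
                a_rmsf["rmsf_A"].to_numpy() - b_rmsf["rmsf_A"].to_numpy()
            ),
        }
    )
    delta_entropy = {}
    for domain in report_a["entropy"]:
        if domain not in report_b["entropy"]:
            raise GrooveDynError(f"entropy domain {domain!r} missing from reference")
        ea, eb = report_a["entropy"][domain], report_b["entropy"][domain]
        delta_entropy[domain] = {
            "delta_S_J_per_K_mol": ea["S_J_per_K_mol"] - eb["S_J_per_K_mol"],
            "combined_error_J_per_K_mol": ea["convergence_error_J_per_K_mol"]
            + eb["convergence_error_J_per_K_mol"],
        }
    delta_widths = None
    if report_a["widths"] is not None and report_b["widths"] is not None:
        wa = report_a["widths"].set_index("metric")
        wb = report_b["widths"].set_index("metric")
        delta_widths = pd.DataFrame(
            {
                "metric": wa.index,
                "delta_mean_A": wa["mean_A"].to_numpy() - wb["mean_A"].to_numpy(),
                "combined_sem_A": np.sqrt(
                    wa["sem_A"].to_numpy() ** 2 + wb["sem_A"].to_numpy() ** 2
                ),
            }
        )
    delta_forces = None
    if report_a.get("force_matrix") is not None and report_b.get("force_matrix") is not None:
        delta_forces = force_difference_map(
            report_a["force_matrix"], report_b["force_matrix"], floor=floor_pN
        )
        for entry in delta_forces:
            entry["pair"] = "/".join(entry["pair"])
    return {
        "delta_rmsf": delta_rmsf,
        "delta_entropy": delta_entropy,
        "delta_widths": delta_widths,
        "delta_forces": delta_forces,
    }
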