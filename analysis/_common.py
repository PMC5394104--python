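"""Shared helpers for the analysis drivers: system loading and the
replica-exclusion rule (a fully dissociated replica is dropped from all
analyses)."""

from pathlib import Path

from groovedyn.io import read_parameter_table, read_structure, read_trajectory
from groovedyn.select import select
from groovedyn.superpose import fit_trajectory, flag_full_dissociation, residue_rmsd_series

RESULTS = Path("results")
SCRATCH = Path("scratch/trajectories")
THRESHOLD_A = 3.0
PERSISTENCE_NS = 0.01


def load_system(name: str, with_parameters: bool = False):
    top, ref = read_structure(RESULTS / "systems" / f"{name}.pdb")
    if with_parameters:
        top = top.with_parameters(
            read_parameter_table(RESULTS / "systems" / f"{name}_params.csv")
        )
    return top, ref


def retained_replicas(name: str, top, ref):
    """Replica trajectories with the full-dissociation exclusion applied."""
    fit_sel = select(top, "chain M and name CA")
    measure_sel = select(top, "chain P and name CA")
    kept = []
    for path in sorted(SCRATCH.glob(f"{name}_rep*.traj")):
        traj = read_trajectory(path, top)
        fitted = fit_trajectory(traj, ref, fit_sel)
        labels, s = residue_rmsd_series(fitted, ref, measure_sel)
        if flag_full_dissociation(
            s, fitted.times, labels, labels[0], labels[-1],
            threshold=THRESHOLD_A, persistence_ns=PERSISTENCE_NS,
        ):
            print(f"{name}: replica {path.name} fully dissociated -> excluded")
            continue
        kept.append(traj)
    if not kept:
        raise SystemExit(f"{name}: every replica was excluded")
    return kept
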