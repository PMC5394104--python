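#!/usr/bin/env python
"""Build the synthetic study systems and generate replica trajectories.

Two systems mirror the loaded / C-terminally truncated comparison: the
full-length 9-mer peptide bound in the toy groove ("full"), and the same
system with the C-terminal anchor bead removed ("d1c").  Five Langevin
replicas are run per system.  Structures and parameter tables (small,
text) go to results/systems/; trajectories go to scratch/trajectories/.

Run from the repository root:  python analysis/01_build_systems.py
"""

from pathlib import Path

from groovedyn.io import write_parameter_table, write_structure, write_trajectory_fixture
from groovedyn.synthetic import (
    LangevinSpec,
    build_toy_groove,
    propagate_langevin,
    truncate_peptide,
)

RESULTS = Path("results/systems")
SCRATCH = Path("scratch/trajectories")
N_REPLICAS = 5
BASE_SEED = 20260930


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    full = build_toy_groove()
    systems = {"full": full, "d1c": truncate_peptide(*full, n_remove_c=1)}
    for name, (top, frame, rows) in systems.items():
        write_structure(RESULTS / f"{name}.pdb", top, frame)
        write_parameter_table(RESULTS / f"{name}_params.csv", rows)
        for r in range(N_REPLICAS):
            seed = BASE_SEED + 1000 * r + (0 if name == "full" else 500)
            traj = propagate_langevin(top, frame, LangevinSpec(seed=seed))
            out = SCRATCH / f"{name}_rep{r}.traj"
            write_trajectory_fixture(out, traj)
            print(f"{name} replica {r}: {traj.n_frames} frames -> {out}")
    print(f"structures and parameters in {RESULTS}/, trajectories in {SCRATCH}/")


if __name__ == "__main__":
    main()
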