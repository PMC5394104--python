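"""Structure, trajectory and parameter-table I/O.

Structures are read from PDB (ATOM/HETATM records) or from a plain-text
fixture dialect; trajectories from XTC and DCD (via mdtraj's low-level
format readers) or from a whitespace text fixture dialect, so that tests
need no binary files.  All coordinates are converted to Angstrom and all
times to nanoseconds at this boundary.

Fixture trajectory dialect::

    # groovedyn trajectory fixture
    frame 0 time 0.0
    x y z          <- one line per atom, Angstrom
    ...
    frame 1 time 0.01
    ...

Fixture structure dialect: one line per atom,
``chain residue_seq residue_name atom_name element x y z``.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np

from .model import (
    AtomRecord,
    GrooveDynError,
    Topology,
    TopologyError,
    Trajectory,
    mass_for_element,
)

__all__ = [
    "FormatError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory_fixture",
    "read_parameter_table",
    "write_parameter_table",
]


class FormatError(GrooveDynError):
    """Unparsable file content; message names the offending line."""


# ---------------------------------------------------------------------------
# structures


def _parse_pdb_line(line: str, lineno: int, index: int, residue_counter: dict) -> AtomRecord:
    try:
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        residue_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 77 else ""
    except (ValueError, IndexError) as exc:
        raise FormatError(f"unparsable PDB record at line {lineno}: {line.rstrip()!r}") from exc
    rid = (chain_id, residue_seq, residue_name)
    if rid not in residue_counter:
        residue_counter[rid] = len(residue_counter)
    record = AtomRecord(
        index=index,
        name=name,
        element=element,
        mass=mass_for_element(element, name),
        residue_index=residue_counter[rid],
        residue_name=residue_name,
        residue_seq=residue_seq,
        chain_id=chain_id,
    )
    return record, (x, y, z)


def read_structure(path: str | Path) -> tuple[Topology, np.ndarray]:
    """Read a PDB file (or the fixture structure dialect) into a
    :class:`Topology` plus one N x 3 coordinate frame in Angstrom.

    Masses are assigned from the element column, falling back to the
    first character of the atom name.  Duplicate (chain, residue number,
    atom name) triples raise a :class:`~groovedyn.model.TopologyError`.
    """
    path = Path(path)
    text = path.read_text()
    if any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
        return _read_pdb(text)
    return _read_structure_fixture(text, path)


def _read_pdb(text: str) -> tuple[Topology, np.ndarray]:
    atoms: list[AtomRecord] = []
    coords: list[tuple[float, float, float]] = []
    residue_counter: dict = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        record, xyz = _parse_pdb_line(line, lineno, len(atoms), residue_counter)
        atoms.append(record)
        coords.append(xyz)
    if not atoms:
        raise FormatError("no ATOM/HETATM records found")
    return Topology(atoms=atoms), np.array(coords, dtype=np.float64)


def _read_structure_fixture(text: str, path: Path) -> tuple[Topology, np.ndarray]:
    atoms: list[AtomRecord] = []
    coords: list[tuple[float, float, float]] = []
    residue_counter: dict = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 8:
            raise FormatError(f"unparsable structure record at line {lineno} of {path.name}")
        try:
            chain, seq, resname, name, element = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            xyz = tuple(float(v) for v in parts[5:8])
        except ValueError as exc:
            raise FormatError(
                f"unparsable structure record at line {lineno} of {path.name}"
            ) from exc
        rid = (chain, seq, resname)
        if rid not in residue_counter:
            residue_counter[rid] = len(residue_counter)
        atoms.append(
            AtomRecord(
                index=len(atoms),
                name=name,
                element=element,
                mass=mass_for_element(element, name),
                residue_index=residue_counter[rid],
                residue_name=resname,
                residue_seq=seq,
                chain_id=chain,
            )
        )
        coords.append(xyz)
    if not atoms:
        raise FormatError(f"no atom records found in {path.name}")
    return Topology(atoms=atoms), np.array(coords, dtype=np.float64)


def write_structure(path: str | Path, topology: Topology, frame: np.ndarray) -> None:
    """Write a minimal PDB file (ATOM records only)."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != (topology.n_atoms, 3):
        raise GrooveDynError("frame shape does not match topology")
    lines = []
    for atom, (x, y, z) in zip(topology.atoms, frame):
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
        lines.append(
            f"ATOM  {atom.index + 1:>5d} {name:<4s} {atom.residue_name:<3s} "
            f"{atom.chain_id:1s}{atom.residue_seq:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{atom.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trajectories


def read_trajectory(
    path: str | Path,
    topology: Topology,
    stride_ps: float | None = None,
) -> Trajectory:
    """Read an XTC, DCD or fixture-text trajectory.

    Coordinates are returned in Angstrom regardless of the on-disk unit
    (XTC stores nm).  Times come from the file when it carries them
    (XTC), otherwise from ``stride_ps`` (frame spacing in picoseconds,
    default 10 ps).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xtc":
        import mdtraj.formats

        with mdtraj.formats.XTCTrajectoryFile(str(path)) as fh:
            xyz, time_ps, _, _ = fh.read()
        coords = np.asarray(xyz, dtype=np.float64) * 10.0  # nm -> Angstrom
        times = np.asarray(time_ps, dtype=np.float64) / 1000.0  # ps -> ns
        if times.size > 1 and not np.all(np.diff(times) > 0):
            times = _times_from_stride(coords.shape[0], stride_ps)
    elif suffix == ".dcd":
        import mdtraj.formats

        with mdtraj.formats.DCDTrajectoryFile(str(path)) as fh:
            xyz, _, _ = fh.read()
        coords = np.asarray(xyz, dtype=np.float64)  # DCD is Angstrom
        times = _times_from_stride(coords.shape[0], stride_ps)
    else:
        coords, times = _read_trajectory_fixture(path, topology.n_atoms)
        if times is None:
            times = _times_from_stride(coords.shape[0], stride_ps)
    if coords.shape[1] != topology.n_atoms:
        raise TopologyError(
            f"trajectory {path.name} has {coords.shape[1]} atoms per frame but the "
            f"topology has {topology.n_atoms}"
        )
    return Trajectory(coordinates=coords, times=times, topology=topology)


def _times_from_stride(n_frames: int, stride_ps: float | None) -> np.ndarray:
    stride = 10.0 if stride_ps is None else float(stride_ps)
    return (np.arange(1, n_frames + 1) * stride) / 1000.0


def _read_trajectory_fixture(
    path: Path, n_atoms: int
) -> tuple[np.ndarray, np.ndarray | None]:
    frames: list[list[tuple[float, float, float]]] = []
    times: list[float] = []
    current: list[tuple[float, float, float]] | None = None
    have_times = True
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.startswith("frame"):
            if current is not None:
                frames.append(current)
            parts = stripped.split()
            if "time" in parts:
                times.append(float(parts[parts.index("time") + 1]))
            else:
                have_times = False
            current = []
            continue
        if current is None:
            raise FormatError(f"coordinate line before any frame header at line {lineno}")
        parts = stripped.split()
        if len(parts) != 3:
            raise FormatError(f"unparsable coordinate record at line {lineno}: {stripped!r}")
        try:
            current.append(tuple(float(v) for v in parts))
        except ValueError as exc:
            raise FormatError(
                f"unparsable coordinate record at line {lineno}: {stripped!r}"
            ) from exc
    if current is not None:
        frames.append(current)
    if not frames:
        raise FormatError(f"no frames found in {path.name}")
    if len(frames[-1]) != n_atoms:
        warnings.warn(
            f"dropping truncated final frame of {path.name} "
            f"({len(frames[-1])}/{n_atoms} atoms)",
            stacklevel=3,
        )
        frames = frames[:-1]
        times = times[: len(frames)]
        if not frames:
            raise FormatError(f"no complete frames in {path.name}")
    for i, fr in enumerate(frames):
        if len(fr) != n_atoms:
            raise TopologyError(
                f"frame {i} of {path.name} has {len(fr)} atoms, expected {n_atoms}"
            )
    coords = np.array(frames, dtype=np.float64)
    return coords, (np.array(times) if have_times and len(times) == len(frames) else None)


def write_trajectory_fixture(path: str | Path, traj: Trajectory) -> None:
    """Write the plain-text fixture trajectory dialect (full double precision)."""
    lines = ["# groovedyn trajectory fixture"]
    for f in range(traj.n_frames):
        lines.append(f"frame {f} time {traj.times[f]:.17g}")
        for x, y, z in traj.coordinates[f]:
            lines.append(f"{x:.17g} {y:.17g} {z:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# parameter tables (charges / Lennard-Jones)


def read_parameter_table(path: str | Path) -> list[tuple[str, int, str, float, float, float]]:
    """Read a per-atom parameter CSV with columns
    ``chain,residue_seq,atom_name,charge,sigma,epsilon``
    (charge in e, sigma in Angstrom, epsilon in kJ/mol)."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"chain", "residue_seq", "atom_name", "charge", "sigma", "epsilon"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(
                f"parameter table must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                rows.append(
                    (
                        row["chain"],
                        int(row["residue_seq"]),
                        row["atom_name"],
                        float(row["charge"]),
                        float(row["sigma"]),
                        float(row["epsilon"]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"unparsable parameter row at line {i}") from exc
    return rows


def write_parameter_table(
    path: str | Path, rows: list[tuple[str, int, str, float, float, float]]
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["chain", "residue_seq", "atom_name", "charge", "sigma", "epsilon"])
        for row in rows:
            writer.writerow(row)
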