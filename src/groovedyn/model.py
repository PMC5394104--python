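"""Core domain types: atoms, topologies, trajectories and atom selections.

Conventions used throughout the package:

* coordinates are stored in Angstrom, times in nanoseconds, masses in
  unified atomic mass units (u); unit conversion happens only at I/O
  boundaries;
* atom and residue indices are 0-based internally, while the
  author-assigned PDB residue number (``residue_seq``, 1-based) is kept
  for reporting so outputs can name residues the way structural
  biologists do ("Y84", "T138").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "Trajectory",
    "Selection",
    "GrooveDynError",
    "TopologyError",
    "ELEMENT_MASSES",
    "residue_label",
]


class GrooveDynError(Exception):
    """Base class for all errors raised by this package."""


class TopologyError(GrooveDynError):
    """Inconsistent or invalid topology."""


#: Standard atomic masses (u) for the elements that occur in proteins and
#: in the coarse-grained fixtures.  Source: IUPAC 2021 standard weights.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "NA": 22.990,
    "CL": 35.45,
    "MG": 24.305,
    "ZN": 65.38,
    "FE": 55.845,
    "CA": 40.078,  # the element calcium, not the alpha carbon
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def mass_for_element(element: str, atom_name: str = "") -> float:
    """Look up the atomic mass for ``element``, falling back to the first
    character of the atom name when the element field is absent."""
    key = element.strip().upper()
    if key in ELEMENT_MASSES:
        return ELEMENT_MASSES[key]
    if atom_name:
        first = atom_name.strip()[0].upper()
        if first in ELEMENT_MASSES:
            return ELEMENT_MASSES[first]
    raise TopologyError(f"cannot assign a mass for element {element!r} / atom {atom_name!r}")


def residue_label(residue_name: str, residue_seq: int) -> str:
    """Human-readable residue label, e.g. ``TYR 85`` -> ``Y85``."""
    one = _THREE_TO_ONE.get(residue_name.upper())
    if one is None:
        return f"{residue_name}{residue_seq}"
    return f"{one}{residue_seq}"


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a topology.

    ``charge`` (e), ``lj_sigma`` (Angstrom) and ``lj_epsilon`` (kJ/mol)
    are optional; they are populated from a parameter table because PDB
    files carry no force-field information.
    """

    index: int
    name: str
    element: str
    mass: float
    residue_index: int
    residue_name: str
    residue_seq: int
    chain_id: str
    charge: float | None = None
    lj_sigma: float | None = None
    lj_epsilon: float | None = None

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise TopologyError(f"atom {self.name}: mass must be positive, got {self.mass}")
        if self.lj_sigma is not None and self.lj_sigma <= 0:
            raise TopologyError(f"atom {self.name}: lj_sigma must be positive")
        if self.lj_epsilon is not None and self.lj_epsilon < 0:
            raise TopologyError(f"atom {self.name}: lj_epsilon must be non-negative")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.name)


@dataclass
class Topology:
    """Ordered list of atoms grouped into residues.

    Residue spans partition the atom list; atom order within residues is
    preserved from the source file.
    """

    atoms: list[AtomRecord]
    residues: list[tuple[str, int, str]] = field(default_factory=list)
    _spans: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for atom in self.atoms:
            if atom.key in seen:
                raise TopologyError(
                    f"duplicate atom (chain {atom.chain_id!r}, residue {atom.residue_seq}, "
                    f"name {atom.name!r})"
                )
            seen.add(atom.key)
        if not self.residues:
            self._rebuild_residues()

    def _rebuild_residues(self) -> None:
        self.residues = []
        self._spans = []
        start = 0
        current: tuple[str, int, str] | None = None
        for i, atom in enumerate(self.atoms):
            rid = (atom.chain_id, atom.residue_seq, atom.residue_name)
            if rid != current:
                if current is not None:
                    self.residues.append(current)
                    self._spans.append((start, i))
                current = rid
                start = i
        if current is not None:
            self.residues.append(current)
            self._spans.append((start, len(self.atoms)))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_span(self, residue_index: int) -> tuple[int, int]:
        return self._spans[residue_index]

    def residue_atoms(self, residue_index: int) -> list[AtomRecord]:
        lo, hi = self._spans[residue_index]
        return self.atoms[lo:hi]

    def residue_label(self, residue_index: int) -> str:
        chain, seq, name = self.residues[residue_index]
        return residue_label(name, seq)

    def masses(self, indices: Sequence[int] | None = None) -> np.ndarray:
        if indices is None:
            return np.array([a.mass for a in self.atoms])
        return np.array([self.atoms[i].mass for i in indices])

    def atom_index(self, chain_id: str, residue_seq: int, name: str) -> int:
        """Resolve an author-numbered atom spec to a 0-based atom index."""
        for atom in self.atoms:
            if atom.key == (chain_id, residue_seq, name):
                return atom.index
        raise TopologyError(
            f"no atom (chain {chain_id!r}, residue {residue_seq}, name {name!r}) in topology"
        )

    def with_parameters(
        self, table: Iterable[tuple[str, int, str, float, float, float]]
    ) -> "Topology":
        """Return a copy with charges / LJ parameters assigned from
        ``(chain, residue_seq, atom name, charge, sigma, epsilon)`` rows."""
        lookup = {(c, s, n): (q, sig, eps) for c, s, n, q, sig, eps in table}
        atoms = []
        for atom in self.atoms:
            if atom.key in lookup:
                q, sig, eps = lookup[atom.key]
                atoms.append(replace(atom, charge=q, lj_sigma=sig, lj_epsilon=eps))
            else:
                atoms.append(atom)
        return Topology(atoms=atoms)


@dataclass
class Trajectory:
    """F frames x N atoms x 3 Cartesian coordinates (Angstrom) with frame
    timestamps in nanoseconds."""

    coordinates: np.ndarray
    times: np.ndarray
    topology: Topology

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise GrooveDynError(
                f"coordinates must be F x N x 3, got shape {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] < 1:
            raise GrooveDynError("trajectory must contain at least one frame")
        if not np.all(np.isfinite(self.coordinates)):
            raise GrooveDynError("trajectory contains non-finite coordinates")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"trajectory has {self.coordinates.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if self.times.shape != (self.coordinates.shape[0],):
            raise GrooveDynError("times must have one entry per frame")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise GrooveDynError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def discard_equilibration(self, t_equil_ns: float) -> "Trajectory":
        """Drop frames with time < ``t_equil_ns`` (equilibration discard)."""
        keep = self.times >= t_equil_ns
        if not np.any(keep):
            raise GrooveDynError(
                f"equilibration discard of {t_equil_ns} ns removes every frame"
            )
        return Trajectory(self.coordinates[keep], self.times[keep], self.topology)


@dataclass
class Selection:
    """Ordered subset of atom indices with residue grouping.

    ``residue_groups`` partitions ``atom_indices`` by the residue each
    atom belongs to, in residue order.
    """

    atom_indices: np.ndarray
    residue_groups: list[tuple[int, np.ndarray]]
    topology: Topology

    def __post_init__(self) -> None:
        self.atom_indices = np.asarray(self.atom_indices, dtype=np.intp)
        n = self.topology.n_atoms
        if self.atom_indices.size:
            if self.atom_indices.min() < 0 or self.atom_indices.max() >= n:
                raise GrooveDynError("selection indices out of range")
            if np.any(np.diff(self.atom_indices) <= 0):
                raise GrooveDynError("selection indices must be unique and sorted")

    @classmethod
    def from_indices(cls, topology: Topology, indices: Iterable[int]) -> "Selection":
        idx = np.array(sorted(set(int(i) for i in indices)), dtype=np.intp)
        groups: dict[int, list[int]] = {}
        for i in idx:
            groups.setdefault(topology.atoms[i].residue_index, []).append(int(i))
        residue_groups = [
            (ri, np.array(groups[ri], dtype=np.intp)) for ri in sorted(groups)
        ]
        return cls(atom_indices=idx, residue_groups=residue_groups, topology=topology)

    def __len__(self) -> int:
        return int(self.atom_indices.size)

    @property
    def residue_labels(self) -> list[str]:
        return [self.topology.residue_label(ri) for ri, _ in self.residue_groups]
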