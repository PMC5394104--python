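"""Synthetic systems with known ground truth.

Three generators make every analysis stage testable without MD output:

* a multivariate-Gaussian positional ensemble whose Schlitter entropy is
  known in closed form;
* a two-state (bound / displaced) Markov-chain peptide that emulates
  reversible partial dissociation with known stationary occupancy and
  exponential dwell times;
* a coarse one-bead-per-residue "toy groove" (two wall rows and a floor
  row holding an extended 9-mer peptide anchored at positions 2 and 9 by
  charge pairs) propagated with overdamped Langevin dynamics under the
  package's own nonbonded model.

The toy groove is a qualitative fixture: it reproduces the *pattern*
that deleting an anchor destabilises the central residues, never real
force-field energetics.  All generators are deterministic for a fixed
seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .entropy import A2_TO_M2, ATOMIC_MASS_KG, HBAR, KB, R_GAS
from .model import AtomRecord, GrooveDynError, Selection, Topology, Trajectory
from .pairforce import PN_PER_KJ_MOL_A, ForceModelParams, frame_pair_forces

__all__ = [
    "GaussianEnsembleSpec",
    "TwoStateSpec",
    "ToyGrooveSpec",
    "LangevinSpec",
    "generate_gaussian_ensemble",
    "generate_two_state",
    "build_toy_groove",
    "truncate_peptide",
    "propagate_langevin",
]

KJ_PER_MOL_KELVIN = R_GAS / 1000.0  # k_B in kJ/(mol K)


def _bead(index: int, chain: str, resseq: int, resname: str = "GLY",
          mass: float = 12.011, name: str = "CA") -> AtomRecord:
    return AtomRecord(
        index=index, name=name, element="C", mass=mass,
        residue_index=index, residue_name=resname, residue_seq=resseq,
        chain_id=chain,
    )


# ---------------------------------------------------------------------------
# Gaussian ensemble


@dataclass
class GaussianEnsembleSpec:
    """I.i.d. multivariate-normal fluctuations about a fixed structure.

    Provide either ``variances`` (3N per-coordinate variances, Angstrom^2,
    diagonal covariance) or a full 3N x 3N ``covariance``.  Masses are in
    u, one per atom.
    """

    n_atoms: int
    masses: np.ndarray
    n_frames: int
    seed: int
    temperature: float = 300.0
    variances: np.ndarray | None = None
    covariance: np.ndarray | None = None
    frame_dt_ns: float = 0.01


def _spec_covariance(spec: GaussianEnsembleSpec) -> np.ndarray:
    n3 = 3 * spec.n_atoms
    if (spec.variances is None) == (spec.covariance is None):
        raise GrooveDynError("give exactly one of variances or covariance")
    if spec.variances is not None:
        v = np.asarray(spec.variances, dtype=np.float64)
        if v.shape != (n3,):
            raise GrooveDynError(f"variances must have length {n3}")
        if np.any(v < 0):
            raise GrooveDynError("variances must be non-negative")
        return np.diag(v)
    cov = np.asarray(spec.covariance, dtype=np.float64)
    if cov.shape != (n3, n3):
        raise GrooveDynError(f"covariance must be {n3} x {n3}")
    eig = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    if eig.min() < -1e-10 * max(eig.max(), 1.0):
        raise GrooveDynError("covariance is not positive semi-definite")
    return 0.5 * (cov + cov.T)


def analytic_schlitter_entropy(
    covariance_A2: np.ndarray, masses_u: np.ndarray, temperature: float
) -> float:
    """Closed-form Schlitter entropy (J/(K mol)) of a known covariance."""
    m_kg = np.repeat(np.asarray(masses_u, dtype=np.float64), 3) * ATOMIC_MASS_KG
    sqrt_m = np.sqrt(m_kg)
    weighted = sqrt_m[:, None] * (covariance_A2 * A2_TO_M2) * sqrt_m[None, :]
    lam = np.clip(np.linalg.eigvalsh(weighted), 0.0, None)
    alpha = KB * temperature * np.e**2 / HBAR**2
    return float(0.5 * R_GAS * np.log1p(alpha * lam).sum())


def generate_gaussian_ensemble(
    spec: GaussianEnsembleSpec,
) -> tuple[Topology, Trajectory, float]:
    """Sample i.i.d. frames about a fixed mean structure.

    Returns ``(topology, trajectory, analytic_entropy)`` where the
    analytic entropy is the Schlitter value of the *specified* covariance
    in J/(K mol).
    """
    masses = np.asarray(spec.masses, dtype=np.float64)
    if masses.shape != (spec.n_atoms,):
        raise GrooveDynError(f"need {spec.n_atoms} masses")
    if spec.n_frames < 2:
        raise GrooveDynError("n_frames must be at least 2")
    cov = _spec_covariance(spec)
    atoms = [_bead(i, "A", i + 1, mass=float(masses[i])) for i in range(spec.n_atoms)]
    topology = Topology(atoms=atoms)
    base = np.zeros((spec.n_atoms, 3))
    base[:, 0] = 10.0 * np.arange(spec.n_atoms)  # well separated along x
    rng = np.random.default_rng(spec.seed)
    if spec.variances is not None:
        noise = rng.standard_normal((spec.n_frames, 3 * spec.n_atoms))
        noise *= np.sqrt(np.asarray(spec.variances, dtype=np.float64))
    else:
        noise = rng.multivariate_normal(
            np.zeros(3 * spec.n_atoms), cov, size=spec.n_frames, method="eigh"
        )
    coords = base[None, :, :] + noise.reshape(spec.n_frames, spec.n_atoms, 3)
    times = spec.frame_dt_ns * np.arange(1, spec.n_frames + 1)
    traj = Trajectory(coordinates=coords, times=times, topology=topology)
    return topology, traj, analytic_schlitter_entropy(cov, masses, spec.temperature)


# ---------------------------------------------------------------------------
# two-state bound / partially-dissociated peptide


@dataclass
class TwoStateSpec:
    """Per-residue two-state (bound/unbound) Markov chains sampled at the
    frame spacing.

    ``k_off`` / ``k_on`` are switching rates in 1/microsecond, either
    scalars (shared by all tagged residues) or one value per tagged
    residue.  The unbound state displaces the residue by ``displacement``
    Angstrom along +z on top of isotropic Gaussian noise.
    """

    k_off: float | np.ndarray
    k_on: float | np.ndarray
    displacement: float = 8.0
    noise_sigma: float = 0.3
    frame_dt_ns: float = 0.1
    n_frames: int = 10000
    seed: int = 0
    n_residues: int = 9
    tagged_residues: tuple[int, ...] | None = None  # 1-based; default: all


def generate_two_state(
    spec: TwoStateSpec,
) -> tuple[Topology, Trajectory, np.ndarray, np.ndarray]:
    """Sample the two-state peptide.

    Returns ``(topology, trajectory, states, stationary_bound)`` where
    ``states`` is (n_frames, n_tagged) with 0 = bound and 1 = unbound and
    ``stationary_bound`` is the per-tagged-residue stationary bound
    fraction ``k_on / (k_on + k_off)``.

    The chain is sampled exactly at frame boundaries from the 2 x 2
    transition matrix of the continuous-time generator, so dwell times
    carry no discretisation bias; the initial state is drawn from the
    stationary law.
    """
    tagged = spec.tagged_residues or tuple(range(1, spec.n_residues + 1))
    n_tag = len(tagged)
    k_off = np.broadcast_to(np.asarray(spec.k_off, dtype=np.float64), (n_tag,))
    k_on = np.broadcast_to(np.asarray(spec.k_on, dtype=np.float64), (n_tag,))
    if np.any(k_off <= 0) or np.any(k_on <= 0):
        raise GrooveDynError("switching rates must be positive")
    atoms = [_bead(i, "P", i + 1) for i in range(spec.n_residues)]
    topology = Topology(atoms=atoms)
    base = np.zeros((spec.n_residues, 3))
    base[:, 0] = 3.8 * np.arange(spec.n_residues)
    rng = np.random.default_rng(spec.seed)
    dt_us = spec.frame_dt_ns / 1000.0
    s = k_off + k_on
    decay = 1.0 - np.exp(-s * dt_us)
    p_off = k_off / s * decay  # bound -> unbound
    p_on = k_on / s * decay  # unbound -> bound
    pi_bound = k_on / s
    states = np.empty((spec.n_frames, n_tag), dtype=np.int8)
    current = (rng.random(n_tag) >= pi_bound).astype(np.int8)
    u = rng.random((spec.n_frames, n_tag))
    for f in range(spec.n_frames):
        flip = np.where(current == 0, u[f] < p_off, u[f] < p_on)
        current = np.where(flip, 1 - current, current).astype(np.int8)
        states[f] = current
    coords = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    coords += rng.normal(0.0, spec.noise_sigma, size=coords.shape)
    tag_idx = np.array([t - 1 for t in tagged])
    coords[:, tag_idx, 2] += spec.displacement * states
    times = spec.frame_dt_ns * np.arange(1, spec.n_frames + 1)
    traj = Trajectory(coordinates=coords, times=times, topology=topology)
    return topology, traj, states, pi_bound


# ---------------------------------------------------------------------------
# toy groove fixture


@dataclass
class ToyGrooveSpec:
    """Coarse-grained groove: two wall bead rows plus a floor row, with an
    extended peptide whose anchor beads pair with charged floor beads."""

    n_wall: int = 12
    peptide_length: int = 9
    anchor_positions: tuple[int, ...] = (2, 9)  # 1-based peptide positions
    anchor_charge: float = -0.6  # e, on the peptide anchor bead
    cage_fraction: float = 0.6  # fraction of |anchor_charge| on flanking floor beads
    lj_sigma: float = 3.0  # Angstrom, all beads
    lj_epsilon: float = 0.3  # kJ/mol
    bead_spacing: float = 3.8  # Angstrom along the groove axis
    wall_half_width: float = 4.5  # Angstrom, wall offset from the axis
    wall_height: float = 3.0  # Angstrom, z of the wall rows
    peptide_height: float = 3.0  # Angstrom, z of the peptide row


def _pair_equilibrium_distance(q: float, sigma: float, epsilon: float) -> float:
    """Distance where LJ repulsion balances Coulomb attraction for an
    opposite-charge contact pair (bisection on the radial force)."""
    from .pairforce import COULOMB_K

    def radial(r: float) -> float:
        sr6 = (sigma / r) ** 6
        return 24.0 * epsilon * (2.0 * sr6**2 - sr6) / r - COULOMB_K * q * q / r**2

    lo, hi = 0.5 * sigma, 2.0 * sigma
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if radial(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def build_toy_groove(
    spec: ToyGrooveSpec = ToyGrooveSpec(),
) -> tuple[Topology, np.ndarray, list[tuple[str, int, str, float, float, float]]]:
    """Build the toy groove scaffold (chain M) plus peptide (chain P).

    Returns ``(topology, frame, parameter_rows)``; the parameter rows use
    the standard parameter-table schema (chain, residue_seq, atom name,
    charge, sigma, epsilon).  Anchor beads carry ``anchor_charge`` and
    the facing floor bead carries the opposite charge, so each anchor
    sits in an electrostatic pocket.
    """
    if spec.peptide_length < 3:
        raise GrooveDynError("peptide must have at least 3 beads")
    if any(not 1 <= a <= spec.peptide_length for a in spec.anchor_positions):
        raise GrooveDynError("anchor positions must lie within the peptide")
    atoms: list[AtomRecord] = []
    coords: list[tuple[float, float, float]] = []

    def add(chain: str, resseq: int, xyz: tuple[float, float, float]) -> None:
        atoms.append(_bead(len(atoms), chain, resseq))
        coords.append(xyz)

    dx = spec.bead_spacing
    for i in range(spec.n_wall):  # left wall: M 1..n
        add("M", i + 1, (i * dx, -spec.wall_half_width, spec.wall_height))
    for i in range(spec.n_wall):  # right wall: M n+1..2n
        add("M", spec.n_wall + i + 1, (i * dx, spec.wall_half_width, spec.wall_height))
    floor_first = 2 * spec.n_wall + 1
    for i in range(spec.n_wall):  # floor: M 2n+1..3n
        add("M", floor_first + i, (i * dx, 0.0, 0.0))
    # extended peptide centred along the groove axis
    offset = 0.5 * (spec.n_wall - spec.peptide_length) * dx
    for i in range(spec.peptide_length):
        add("P", i + 1, (offset + i * dx, 0.0, spec.peptide_height))
    topology = Topology(atoms=atoms)
    frame = np.array(coords, dtype=np.float64)

    charges: dict[tuple[str, int], float] = {}
    floor_last = floor_first + spec.n_wall - 1
    # contact distance at which the LJ repulsion balances the Coulomb
    # attraction of the anchor/partner pair, so the anchor starts at rest
    r_eq = _pair_equilibrium_distance(
        abs(spec.anchor_charge), spec.lj_sigma, spec.lj_epsilon
    )
    for pos in spec.anchor_positions:
        charges[("P", pos)] = spec.anchor_charge
        anchor_x = offset + (pos - 1) * dx
        partner = floor_first + int(round(anchor_x / dx))
        partner = min(max(partner, floor_first), floor_last)
        charges[("M", partner)] = -spec.anchor_charge
        # raise the pocket bead so the anchor's initial position is its
        # force equilibrium
        frame[partner - 1] = (anchor_x, 0.0, spec.peptide_height - r_eq)
        # cage the pocket: flanking floor beads carry a like charge so
        # they repel the anchor and stop it swinging around or hopping off
        # its single partner
        for nb in (partner - 1, partner + 1):
            if floor_first <= nb <= floor_last and ("M", nb) not in charges:
                charges[("M", nb)] = spec.anchor_charge * spec.cage_fraction
    rows = [
        (a.chain_id, a.residue_seq, a.name,
         charges.get((a.chain_id, a.residue_seq), 0.0),
         spec.lj_sigma, spec.lj_epsilon)
        for a in topology.atoms
    ]
    return topology.with_parameters(rows), frame, rows


def truncate_peptide(
    topology: Topology,
    frame: np.ndarray,
    parameter_rows: list[tuple[str, int, str, float, float, float]],
    n_remove_c: int = 1,
    peptide_chain: str = "P",
) -> tuple[Topology, np.ndarray, list[tuple[str, int, str, float, float, float]]]:
    """Remove ``n_remove_c`` residues from the peptide C-terminus,
    keeping topology, coordinates and parameter table consistent."""
    pep_seqs = sorted({a.residue_seq for a in topology.atoms if a.chain_id == peptide_chain})
    if n_remove_c >= len(pep_seqs):
        raise GrooveDynError("cannot remove the whole peptide")
    removed = set(pep_seqs[-n_remove_c:])

    def gone(chain: str, seq: int) -> bool:
        return chain == peptide_chain and seq in removed

    keep = [i for i, a in enumerate(topology.atoms) if not gone(a.chain_id, a.residue_seq)]
    atoms = []
    res_map: dict = {}
    for new_i, old_i in enumerate(keep):
        a = topology.atoms[old_i]
        rid = (a.chain_id, a.residue_seq, a.residue_name)
        if rid not in res_map:
            res_map[rid] = len(res_map)
        atoms.append(
            AtomRecord(
                index=new_i, name=a.name, element=a.element, mass=a.mass,
                residue_index=res_map[rid], residue_name=a.residue_name,
                residue_seq=a.residue_seq, chain_id=a.chain_id,
                charge=a.charge, lj_sigma=a.lj_sigma, lj_epsilon=a.lj_epsilon,
            )
        )
    rows = [r for r in parameter_rows if not gone(r[0], r[1])]
    return Topology(atoms=atoms), np.asarray(frame)[keep].copy(), rows


# ---------------------------------------------------------------------------
# overdamped Langevin propagator


@dataclass
class LangevinSpec:
    """Overdamped (Brownian) dynamics parameters.

    Friction gamma is in kJ mol^-1 ps A^-2 so the per-step mobility is
    ``dt/gamma`` (A^2 mol/kJ); the update is
    ``x += (dt/gamma) F + sqrt(2 kBT dt/gamma) xi``.  ``dt`` must keep
    ``(dt/gamma) * k`` well below 1 for the stiffest effective spring k,
    in practice at most about 0.01 of the fastest harmonic period.
    """

    temperature: float = 300.0
    friction: float = 50.0  # kJ mol^-1 ps A^-2
    dt_ps: float = 0.004
    n_steps: int = 40000
    sample_every: int = 100
    seed: int = 0
    scaffold_k: float = 200.0  # kJ mol^-1 A^-2 restraint on non-peptide beads
    bond_k: float = 200.0  # kJ mol^-1 A^-2 between consecutive peptide beads
    bond_r0: float = 3.75  # Angstrom; slight pre-tension keeps the bound chain taut
    peptide_chain: str = "P"
    model: ForceModelParams = field(default_factory=ForceModelParams)


class LangevinInstabilityError(GrooveDynError):
    """Coordinates diverged; use a smaller time step."""


def propagate_langevin(
    topology: Topology, frame: np.ndarray, spec: LangevinSpec
) -> Trajectory:
    """Propagate the toy system with overdamped Langevin dynamics.

    Scaffold (non-peptide) beads are restrained harmonically to their
    initial positions; consecutive peptide beads are joined by harmonic
    bonds; peptide-scaffold interactions use the nonbonded LJ+Coulomb
    model.  Frames are recorded every ``sample_every`` steps with times
    in ns.  Deterministic for a fixed seed.
    """
    x = np.asarray(frame, dtype=np.float64).copy()
    if x.shape != (topology.n_atoms, 3):
        raise GrooveDynError("frame shape does not match topology")
    rng = np.random.default_rng(spec.seed)
    mu = spec.dt_ps / spec.friction
    kbt = KJ_PER_MOL_KELVIN * spec.temperature
    noise_scale = np.sqrt(2.0 * kbt * mu)
    is_pep = np.array([a.chain_id == spec.peptide_chain for a in topology.atoms])
    pep_idx = np.nonzero(is_pep)[0]
    scaf_idx = np.nonzero(~is_pep)[0]
    x0_scaf = x[scaf_idx].copy()
    # consecutive peptide beads (by residue_seq order within the chain)
    order = pep_idx[np.argsort([topology.atoms[i].residue_seq for i in pep_idx])]
    bonds = list(zip(order[:-1], order[1:]))
    sel_pep = Selection.from_indices(topology, pep_idx) if pep_idx.size else None
    sel_scaf = Selection.from_indices(topology, scaf_idx) if scaf_idx.size else None

    frames = []
    times = []
    for step in range(1, spec.n_steps + 1):
        f = np.zeros_like(x)
        if scaf_idx.size:
            f[scaf_idx] -= spec.scaffold_k * (x[scaf_idx] - x0_scaf)
        for i, j in bonds:
            d = x[i] - x[j]
            r = np.linalg.norm(d)
            if r > 0:
                f_bond = -spec.bond_k * (r - spec.bond_r0) * d / r
                f[i] += f_bond
                f[j] -= f_bond
        if sel_pep is not None and sel_scaf is not None:
            ia, ib, forces_pn = frame_pair_forces(x, topology, sel_pep, sel_scaf, spec.model)
            if forces_pn.size:
                forces = forces_pn / PN_PER_KJ_MOL_A
                np.add.at(f, ia, forces)
                np.add.at(f, ib, -forces)
        x = x + mu * f + noise_scale * rng.standard_normal(x.shape)
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e4:
            raise LangevinInstabilityError(
                f"coordinates diverged at step {step}; reduce dt (currently "
                f"{spec.dt_ps} ps) or increase friction"
            )
        if step % spec.sample_every == 0:
            frames.append(x.copy())
            times.append(step * spec.dt_ps / 1000.0)
    if not frames:
        raise GrooveDynError("n_steps too small: no frames sampled")
    return Trajectory(
        coordinates=np.array(frames), times=np.array(times), topology=topology
    )
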