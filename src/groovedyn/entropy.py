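"""Quasi-harmonic configurational entropy (Schlitter upper bound).

The Schlitter estimate treats positional fluctuations as an effective
multivariate Gaussian and bounds the configurational entropy from the
mass-weighted positional covariance::

    S = 0.5 k_B ln det(1 + k_B T e^2 hbar^-2 M^{1/2} C M^{1/2})

with ``M`` the 3N-dimensional diagonal mass matrix and ``C`` the
covariance of the (superposed) Cartesian coordinates.  The determinant
is evaluated through a symmetric eigendecomposition, summing
``ln(1 + alpha * lambda_i)`` per mode, which is numerically stable and
lets small negative round-off eigenvalues be clamped to zero (each then
contributes ``ln 1 = 0``).  Results are reported per mole, J/(K mol).

Convergence is estimated by the subsampling rule used in practice for
long MD runs: recompute S after discarding a random 10% of the frames
and report the absolute difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import GrooveDynError, Selection, Trajectory

__all__ = [
    "KB",
    "HBAR",
    "R_GAS",
    "ATOMIC_MASS_KG",
    "A2_TO_M2",
    "CovarianceResult",
    "EntropyResult",
    "DeltaEntropy",
    "positional_covariance",
    "schlitter_entropy",
    "entropy_convergence_error",
    "delta_entropy",
    "schlitter_mode_term",
]

# CODATA 2018
KB = 1.380649e-23  # J/K
HBAR = 1.054572e-34  # J s
R_GAS = 8.314463  # J/(K mol)
ATOMIC_MASS_KG = 1.66053906660e-27  # kg per u
A2_TO_M2 = 1e-20  # m^2 per Angstrom^2


@dataclass
class CovarianceResult:
    """3N x 3N positional covariance (Angstrom^2) about the time mean."""

    matrix: np.ndarray
    mean_structure: np.ndarray
    n_frames: int
    selection: Selection


@dataclass
class EntropyResult:
    """Schlitter entropy in J/(K mol) with its per-mode spectrum."""

    S: float
    mode_terms: np.ndarray  # ln(1 + alpha * lambda_i), descending
    temperature: float
    masses: np.ndarray
    n_atoms: int
    n_frames: int
    convergence_error: float | None = None


@dataclass
class DeltaEntropy:
    """Entropy difference system minus reference, with conservative
    (summed) convergence error and a reporting floor."""

    delta_S: float
    combined_error: float
    below_floor: bool
    floor: float


def positional_covariance(fitted: Trajectory, selection: Selection) -> CovarianceResult:
    """Population covariance (1/F normalisation) of the 3N stacked
    coordinates of the selection about their time mean.

    The trajectory must already be superposed on the same selection;
    residual rigid drift of the selection centroid above 0.5 Angstrom
    triggers a warning, as overall translation/rotation would otherwise
    dominate the soft modes.  F > 3N is recommended for a full-rank
    estimate and a warning is emitted otherwise.
    """
    if fitted.n_frames < 2:
        raise GrooveDynError("covariance requires at least 2 frames")
    idx = selection.atom_indices
    x = fitted.coordinates[:, idx, :]
    # net rigid drift: compare the selection centroid averaged over the
    # first and last deciles (running means suppress frame-level noise)
    centroid = x.mean(axis=1)
    decile = max(fitted.n_frames // 10, 1)
    drift = float(
        np.linalg.norm(centroid[-decile:].mean(axis=0) - centroid[:decile].mean(axis=0))
    )
    if drift > 0.5:
        warnings.warn(
            f"selection centroid drifts {drift:.2f} A across the trajectory; "
            "did you forget to superpose?",
            stacklevel=2,
        )
    n3 = 3 * idx.size
    if fitted.n_frames <= n3:
        warnings.warn(
            f"only {fitted.n_frames} frames for a {n3}-dimensional covariance; "
            "the estimate is rank-deficient",
            stacklevel=2,
        )
    flat = x.reshape(fitted.n_frames, n3)
    centered = flat - flat.mean(axis=0)
    cov = centered.T @ centered / fitted.n_frames
    cov = 0.5 * (cov + cov.T)
    return CovarianceResult(
        matrix=cov,
        mean_structure=x.mean(axis=0),
        n_frames=fitted.n_frames,
        selection=selection,
    )


def _alpha(temperature: float) -> float:
    """k_B T e^2 / hbar^2 in 1/(kg m^2)."""
    return KB * temperature * np.e**2 / HBAR**2


def schlitter_mode_term(mass_u: float, variance_A2: float, temperature: float) -> float:
    """Closed-form single-mode contribution 0.5 R ln(1 + alpha m sigma^2),
    J/(K mol); useful as an independent check on diagonal covariances."""
    lam = mass_u * ATOMIC_MASS_KG * variance_A2 * A2_TO_M2
    return 0.5 * R_GAS * float(np.log1p(_alpha(temperature) * lam))


def schlitter_entropy(
    cov: CovarianceResult, masses: np.ndarray, temperature: float
) -> EntropyResult:
    """Evaluate the Schlitter upper bound on a covariance result.

    ``masses`` are per-atom (u), matching the covariance selection;
    negative round-off eigenvalues of the mass-weighted covariance are
    clamped to zero.
    """
    masses = np.asarray(masses, dtype=np.float64)
    n_atoms = len(cov.selection)
    if masses.shape != (n_atoms,):
        raise GrooveDynError(
            f"need {n_atoms} masses for the selection, got {masses.shape}"
        )
    if temperature <= 0:
        raise GrooveDynError("temperature must be positive")
    m_kg = np.repeat(masses, 3) * ATOMIC_MASS_KG
    sqrt_m = np.sqrt(m_kg)
    weighted = sqrt_m[:, None] * (cov.matrix * A2_TO_M2) * sqrt_m[None, :]
    lam = np.linalg.eigvalsh(weighted)
    if not np.all(np.isfinite(lam)):
        raise GrooveDynError("non-finite eigenvalue in mass-weighted covariance")
    lam = np.clip(lam, 0.0, None)[::-1]  # descending, clamped
    mode_terms = np.log1p(_alpha(temperature) * lam)
    return EntropyResult(
        S=float(0.5 * R_GAS * mode_terms.sum()),
        mode_terms=mode_terms,
        temperature=temperature,
        masses=masses,
        n_atoms=n_atoms,
        n_frames=cov.n_frames,
    )


def entropy_convergence_error(
    fitted: Trajectory,
    selection: Selection,
    masses: np.ndarray,
    temperature: float,
    drop_fraction: float = 0.10,
    seed: int = 0,
) -> float:
    """|S_full - S_subsample| after discarding a uniformly random
    ``drop_fraction`` of the frames (without replacement).

    For a converged, stationary estimate the subsample barely moves S;
    a drifting trajectory yields a much larger difference.
    """
    if not 0 < drop_fraction < 1:
        raise GrooveDynError("drop_fraction must lie in (0, 1)")
    s_full = schlitter_entropy(
        positional_covariance(fitted, selection), masses, temperature
    ).S
    rng = np.random.default_rng(seed)
    f = fitted.n_frames
    n_drop = int(drop_fraction * f)
    if n_drop == 0:
        return 0.0
    drop = rng.choice(f, size=n_drop, replace=False)
    keep = np.setdiff1d(np.arange(f), drop)
    sub = Trajectory(
        coordinates=fitted.coordinates[keep],
        times=fitted.times[keep],
        topology=fitted.topology,
    )
    s_sub = schlitter_entropy(
        positional_covariance(sub, selection), masses, temperature
    ).S
    return float(abs(s_full - s_sub))


def delta_entropy(
    system: EntropyResult,
    reference: EntropyResult,
    floor: float = 10.0,
) -> DeltaEntropy:
    """Entropy difference ``S_system - S_reference`` with a combined
    (summed, conservative) convergence error.

    Errors below ``floor`` (default 10 J/(K mol)) are flagged as
    sub-floor rather than reported as meaningful.
    """
    if system.n_atoms != reference.n_atoms:
        raise GrooveDynError(
            f"selection size mismatch: {system.n_atoms} vs {reference.n_atoms}"
        )
    if system.temperature != reference.temperature:
        raise GrooveDynError("temperature mismatch between entropy results")
    err_s = system.convergence_error or 0.0
    err_r = reference.convergence_error or 0.0
    combined = err_s + err_r
    return DeltaEntropy(
        delta_S=float(system.S - reference.S),
        combined_error=float(combined),
        below_floor=combined < floor,
        floor=floor,
    )
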