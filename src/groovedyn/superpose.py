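"""Rigid-body superposition and deviation / fluctuation analyses.

Implements weighted Kabsch fitting, trajectory superposition, per-residue
RMSD time series, dissociation classification against a distance
threshold (default 3 Angstrom), bound-time fractions, RMSF, moving
averages, and the replica-exclusion rule for peptides that leave the
binding groove for good.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GrooveDynError, Selection, Trajectory

__all__ = [
    "RigidTransform",
    "DissociationProfile",
    "DegenerateFitError",
    "kabsch_fit",
    "fit_trajectory",
    "residue_rmsd_series",
    "dissociation_profile",
    "bound_fraction_both_termini",
    "rmsf",
    "moving_average",
    "flag_full_dissociation",
    "block_bootstrap_sem",
]


class DegenerateFitError(GrooveDynError):
    """Fit points are collinear or otherwise rank-deficient."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform ``x -> R x + t`` (Angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64)
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise GrooveDynError("rotation must be proper (det = +1)")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-8:
            raise GrooveDynError("rotation must be orthogonal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ np.asarray(self.rotation).T + np.asarray(self.translation)


def kabsch_fit(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> RigidTransform:
    """Optimal proper rigid transform mapping ``mobile`` onto ``reference``.

    Minimises the weighted sum of squared deviations (Kabsch algorithm via
    SVD); the reflection branch is corrected so the rotation determinant
    is +1.  Weights default to equal.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GrooveDynError("mobile and reference must both be M x 3")
    m = mobile.shape[0]
    if m < 3:
        raise DegenerateFitError("at least 3 fit points are required")
    if weights is None:
        w = np.full(m, 1.0 / m)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (m,) or np.any(w < 0) or w.sum() <= 0:
            raise GrooveDynError("weights must be M non-negative values, not all zero")
        w = w / w.sum()
    mob_c = mobile - w @ mobile
    ref_c = reference - w @ reference
    H = (mob_c * w[:, None]).T @ ref_c
    U, s, Vt = np.linalg.svd(H)
    # collinear points give a rank <= 1 cross-covariance: rotation about the
    # line is unconstrained
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise DegenerateFitError("fit points are collinear (degenerate cross-covariance)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    rotation = Vt.T @ D @ U.T
    translation = (w @ reference) - rotation @ (w @ mobile)
    return RigidTransform(rotation=rotation, translation=translation)


def fit_trajectory(
    traj: Trajectory,
    reference: np.ndarray,
    fit_selection: Selection,
    weights: np.ndarray | None = None,
) -> Trajectory:
    """Superpose every frame onto ``reference`` using the fit-selection
    atoms only; the resulting transform is applied to all atoms."""
    if len(fit_selection) == 0:
        raise GrooveDynError("fit selection is empty")
    reference = np.asarray(reference, dtype=np.float64)
    idx = fit_selection.atom_indices
    ref_sub = reference[idx]
    out = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        tf = kabsch_fit(traj.coordinates[f, idx], ref_sub, weights)
        out[f] = tf.apply(traj.coordinates[f])
    return Trajectory(coordinates=out, times=traj.times.copy(), topology=traj.topology)


def residue_rmsd_series(
    fitted: Trajectory,
    reference: np.ndarray,
    measure_selection: Selection,
) -> tuple[list[str], np.ndarray]:
    """Per-frame, per-residue RMSD (Angstrom) of the measure-selection atoms
    from their reference positions.

    The trajectory must already be superposed (fit and measure selections
    are independent: dissociation analyses fit on the receptor frame and
    measure on the peptide).  For single-atom residue groups (C-alpha) the
    per-residue RMSD is simply that atom's displacement.
    Returns ``(residue_labels, F x R array)``.
    """
    if len(measure_selection) == 0:
        raise GrooveDynError("measure selection is empty")
    reference = np.asarray(reference, dtype=np.float64)
    labels = measure_selection.residue_labels
    out = np.empty((fitted.n_frames, len(labels)))
    for r, (_, idx) in enumerate(measure_selection.residue_groups):
        d = fitted.coordinates[:, idx, :] - reference[idx]
        out[:, r] = np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))
    return labels, out


@dataclass
class DissociationProfile:
    """Per-residue dissociation statistics over replicas.

    ``bound_mask`` marks frames at or below the threshold (ties count as
    bound); ``mean_rmsd`` averages over frames within each replica, then
    over replicas with equal weight; ``bound_fraction`` pools all retained
    frames.
    """

    residue_labels: list[str]
    per_frame_rmsd: list[np.ndarray]
    bound_mask: list[np.ndarray]
    mean_rmsd: np.ndarray
    bound_fraction: np.ndarray
    threshold: float


def dissociation_profile(
    series: list[np.ndarray],
    residue_labels: list[str],
    threshold: float = 3.0,
) -> DissociationProfile:
    """Classify per-residue RMSD series from one or more replicas against a
    dissociation threshold (default 3 Angstrom)."""
    if not series:
        raise GrooveDynError("at least one replica series is required")
    if threshold <= 0:
        raise GrooveDynError("threshold must be positive")
    series = [np.asarray(s, dtype=np.float64) for s in series]
    r = len(residue_labels)
    for s in series:
        if s.ndim != 2 or s.shape[1] != r:
            raise GrooveDynError("each replica series must be F x n_residues")
    bound = [s <= threshold for s in series]
    per_replica_mean = np.array([s.mean(axis=0) for s in series])
    pooled_bound = np.concatenate(bound, axis=0)
    return DissociationProfile(
        residue_labels=list(residue_labels),
        per_frame_rmsd=series,
        bound_mask=bound,
        mean_rmsd=per_replica_mean.mean(axis=0),
        bound_fraction=pooled_bound.mean(axis=0),
        threshold=threshold,
    )


def _label_index(profile: DissociationProfile, label: str) -> int:
    try:
        return profile.residue_labels.index(label)
    except ValueError:
        raise GrooveDynError(
            f"unknown residue label {label!r}; have {profile.residue_labels}"
        ) from None


def bound_fraction_both_termini(
    profile: DissociationProfile, n_residue: str, c_residue: str
) -> float:
    """Fraction of frames in which both named terminal residues are
    simultaneously bound (at or below the threshold)."""
    i = _label_index(profile, n_residue)
    j = _label_index(profile, c_residue)
    joint = np.concatenate([b[:, i] & b[:, j] for b in profile.bound_mask])
    return float(joint.mean())


def rmsf(
    fitted: Trajectory, selection: Selection
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Root-mean-square fluctuation about the time-mean position.

    Returns ``(per_atom_rmsf, residue_labels, per_residue_rmsf)``; the
    per-residue value is the C-alpha atom's RMSF when the residue group
    contains one, otherwise the mean over the group's atoms.
    """
    if fitted.n_frames < 2:
        raise GrooveDynError("RMSF is undefined for a single frame")
    idx = selection.atom_indices
    x = fitted.coordinates[:, idx, :]
    mean = x.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0))
    pos_of = {int(a): k for k, a in enumerate(idx)}
    labels = selection.residue_labels
    per_res = np.empty(len(labels))
    for r, (_, atom_idx) in enumerate(selection.residue_groups):
        ca = [i for i in atom_idx if fitted.topology.atoms[i].name.upper() == "CA"]
        chosen = ca if ca else list(atom_idx)
        per_res[r] = np.mean([per_atom[pos_of[int(i)]] for i in chosen])
    return per_atom, labels, per_res


def moving_average(series: np.ndarray, window_ns: float, dt_ns: float) -> np.ndarray:
    """Centred moving average with the window given in nanoseconds.

    Ends are averaged over the available frames, so a constant series is
    returned unchanged.  The window must be at least one frame spacing.
    """
    series = np.asarray(series, dtype=np.float64)
    if window_ns < dt_ns:
        raise GrooveDynError(
            f"window {window_ns} ns is smaller than the frame spacing {dt_ns} ns"
        )
    w = int(round(window_ns / dt_ns))
    w = max(w, 1)
    kernel = np.ones(w)
    summed = np.convolve(series, kernel, mode="same")
    counts = np.convolve(np.ones_like(series), kernel, mode="same")
    return summed / counts


def flag_full_dissociation(
    series: np.ndarray,
    times: np.ndarray,
    residue_labels: list[str],
    n_residue: str,
    c_residue: str,
    threshold: float = 3.0,
    persistence_ns: float = 10.0,
) -> bool:
    """Replica-exclusion rule: ``True`` iff both terminal residues exceed
    the threshold continuously from some time until the trajectory end,
    for at least ``persistence_ns``."""
    if persistence_ns <= 0:
        raise GrooveDynError("persistence must be positive")
    labels = list(residue_labels)
    i = labels.index(n_residue) if n_residue in labels else None
    j = labels.index(c_residue) if c_residue in labels else None
    if i is None or j is None:
        raise GrooveDynError("terminal residue labels not found in series")
    unbound = (series[:, i] > threshold) & (series[:, j] > threshold)
    if not unbound[-1]:
        return False
    # first frame of the terminal all-unbound suffix
    bound_frames = np.nonzero(~unbound)[0]
    start = 0 if bound_frames.size == 0 else int(bound_frames[-1]) + 1
    return float(times[-1] - times[start]) >= persistence_ns


def block_bootstrap_sem(
    series: np.ndarray,
    n_blocks: int = 20,
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    """Standard error of the series mean by bootstrap over contiguous
    blocks, robust to autocorrelation within blocks."""
    series = np.asarray(series, dtype=np.float64)
    n = series.size
    if n < n_blocks:
        raise GrooveDynError("series shorter than the number of blocks")
    block_means = np.array([b.mean() for b in np.array_split(series, n_blocks)])
    rng = np.random.default_rng(seed)
    resampled = rng.choice(block_means, size=(n_boot, n_blocks), replace=True)
    return float(resampled.mean(axis=1).std(ddof=1))
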