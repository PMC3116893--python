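"""Ensemble statistics: superposition, RMSD, fluctuation tensors, PCA,
and reference-structure convergence analysis.

The convergence analysis follows the ensemble-clustering idea of Lyman &
Zuckerman: reference structures are picked at random until every frame
lies within a Cα-RMSD cutoff r of some reference, frames are assigned to
their nearest reference, the trajectory is split into halves by time, and
a *lone reference* is one whose group receives no member from one half —
a symptom of non-convergence. The analysis is repeated for several random
seeds (default 5) for robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import StructureModel, Trajectory, select


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def superpose(mobile, reference, weights=None):
    """Least-squares rigid-body fit (Kabsch, proper rotation only).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``; the
    reported RMSD is the post-fit value (weighted if weights are given).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("need two equal sets of >= 3 points")
    w = np.ones(len(mobile)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    x = mobile - mc
    y = reference - rc
    if np.linalg.matrix_rank(x, tol=1e-9) < 2:
        raise ValueError("mobile points are collinear; fit is degenerate")
    h = (w[:, None] * x).T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    fitted = x @ rot.T + rc
    rmsd = float(np.sqrt((w * ((fitted - reference) ** 2).sum(axis=1)).sum()))
    translation = rc - mc @ rot.T
    return rot, translation, rmsd


def apply_fit(coords, rotation, translation):
    return np.asarray(coords) @ rotation.T + translation


def pairwise_rmsd(frame_a, frame_b, indices=None) -> float:
    """RMSD between two frames after best fit on ``indices`` (default all)."""
    if indices is not None:
        frame_a = frame_a[indices]
        frame_b = frame_b[indices]
    return superpose(frame_a, frame_b)[2]


# ---------------------------------------------------------------------------
# RMSD series and fluctuations
# ---------------------------------------------------------------------------

def _resolve_reference(trajectory: Trajectory, reference, selection):
    if isinstance(reference, str):
        if reference == "first":
            return trajectory.frames[0]
        if reference == "average":
            return average_structure(trajectory, selection=None)
        raise ValueError("reference must be 'first', 'average' or coordinates")
    return np.asarray(reference, dtype=float)


def rmsd_series(
    trajectory: Trajectory,
    reference="first",
    selection=None,
    fit_selection=None,
) -> np.ndarray:
    """Per-frame RMSD (Å) to a reference after rigid-body fit.

    Each frame is fitted on ``fit_selection`` (default: same as
    ``selection``) and the RMSD is reported over ``selection``.
    """
    sel = np.arange(trajectory.topology.n_atoms) if selection is None \
        else np.asarray(selection)
    if len(sel) == 0:
        raise ValueError("empty selection")
    fit_sel = sel if fit_selection is None else np.asarray(fit_selection)
    ref = _resolve_reference(trajectory, reference, selection)
    out = np.empty(trajectory.n_frames)
    for f, frame in enumerate(trajectory.frames):
        rot, trans, _ = superpose(frame[fit_sel], ref[fit_sel])
        fitted = apply_fit(frame[sel], rot, trans)
        out[f] = np.sqrt(((fitted - ref[sel]) ** 2).sum(axis=1).mean())
    return out


def average_structure(
    trajectory: Trajectory, selection=None, n_iter: int = 2
) -> np.ndarray:
    """Iterative best-fit average coordinates (fit → average → refit)."""
    sel = np.arange(trajectory.topology.n_atoms) if selection is None \
        else np.asarray(selection)
    ref = trajectory.frames[0]
    fitted = trajectory.frames
    for _ in range(n_iter):
        fitted = np.empty_like(trajectory.frames)
        for f, frame in enumerate(trajectory.frames):
            rot, trans, _ = superpose(frame[sel], ref[sel])
            fitted[f] = apply_fit(frame, rot, trans)
        ref = fitted.mean(axis=0)
    return ref


def fitted_frames(trajectory: Trajectory, selection=None, n_iter: int = 2):
    """Frames superposed onto the iterative average; returns (frames, average)."""
    sel = np.arange(trajectory.topology.n_atoms) if selection is None \
        else np.asarray(selection)
    avg = average_structure(trajectory, selection=sel, n_iter=n_iter)
    out = np.empty_like(trajectory.frames)
    for f, frame in enumerate(trajectory.frames):
        rot, trans, _ = superpose(frame[sel], avg[sel])
        out[f] = apply_fit(frame, rot, trans)
    return out, avg


@dataclass
class FluctuationTensorSet:
    """Per-atom 3×3 positional covariances (Å²) about the fitted average."""

    tensors: np.ndarray     # (n_sel, 3, 3), symmetric PSD
    atom_indices: np.ndarray
    mean_coords: np.ndarray  # (n_sel, 3)

    @property
    def msf(self) -> np.ndarray:
        """Mean-square fluctuation per atom = trace of its tensor."""
        return np.trace(self.tensors, axis1=1, axis2=2)

    def ellipsoid_axes(self, atom: int):
        """Principal axes (eigenvalues Å², eigenvectors) for drawing."""
        vals, vecs = np.linalg.eigh(self.tensors[atom])
        return vals[::-1], vecs[:, ::-1]


def fluctuation_tensors(trajectory: Trajectory, selection=None) -> FluctuationTensorSet:
    """Anisotropic atomic fluctuations after RMS fit onto the average."""
    if trajectory.n_frames < 2:
        raise ValueError("need at least 2 frames")
    sel = np.arange(trajectory.topology.n_atoms) if selection is None \
        else np.asarray(selection)
    frames, avg = fitted_frames(trajectory, selection=sel)
    dev = frames[:, sel, :] - avg[sel]
    tensors = np.einsum("fai,faj->aij", dev, dev) / trajectory.n_frames
    return FluctuationTensorSet(
        tensors=tensors, atom_indices=sel, mean_coords=avg[sel]
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    mean_structure: np.ndarray       # (n_sel, 3)
    eigenvalues: np.ndarray          # (n_modes,) Å², descending
    eigenvectors: np.ndarray         # (n_modes, 3·n_sel), orthonormal rows
    cumulative_variance: np.ndarray  # (n_modes,) fractions, ends at 1
    atom_indices: np.ndarray

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


def pca(trajectory: Trajectory, selection=None) -> PCAResult:
    """Quasi-harmonic PCA of fitted coordinates on a selection.

    Frames are superposed onto the iterative average conformation, the
    3N×3N positional covariance is diagonalized and modes are sorted by
    descending variance.
    """
    if trajectory.n_frames < 2:
        raise ValueError("need at least 2 frames")
    sel = np.arange(trajectory.topology.n_atoms) if selection is None \
        else np.asarray(selection)
    frames, avg = fitted_frames(trajectory, selection=sel)
    x = frames[:, sel, :].reshape(trajectory.n_frames, -1)
    mu = x.mean(axis=0)
    dev = x - mu
    cov = dev.T @ dev / trajectory.n_frames
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order].T
    total = vals.sum()
    cum = np.cumsum(vals) / total if total > 0 else np.ones_like(vals)
    return PCAResult(
        mean_structure=mu.reshape(-1, 3),
        eigenvalues=vals,
        eigenvectors=vecs,
        cumulative_variance=cum,
        atom_indices=sel,
    )


def n_modes_for_variance(result: PCAResult, fraction: float = 0.9) -> int:
    """Smallest number of PCA modes describing >= ``fraction`` of variance."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return int(np.searchsorted(result.cumulative_variance, fraction - 1e-12) + 1)


# ---------------------------------------------------------------------------
# convergence analysis
# ---------------------------------------------------------------------------

@dataclass
class SeedReport:
    seed: int
    n_references: int
    n_lone_references: int
    reference_frames: list[int]
    assignments: np.ndarray = field(repr=False)


@dataclass
class ConvergenceReport:
    cutoff: float
    seeds: list[int]
    per_seed: list[SeedReport]

    @property
    def n_references(self) -> list[int]:
        return [s.n_references for s in self.per_seed]

    @property
    def n_lone_references(self) -> list[int]:
        return [s.n_lone_references for s in self.per_seed]

    def representative_frames(self) -> list[int]:
        """References of the seed with fewest lone references (for NMA),
        tie-broken toward the earliest-seed run; frames sorted by time."""
        best = min(self.per_seed, key=lambda s: (s.n_lone_references, s.seed))
        return sorted(best.reference_frames)


def convergence_analysis(
    trajectory: Trajectory,
    cutoff: float,
    seeds=(1, 2, 3, 4, 5),
    selection="calpha",
) -> ConvergenceReport:
    """Reference-structure convergence analysis of a trajectory.

    Per seed: (i) pick random frames as references until every frame is
    within ``cutoff`` Å (Cα RMSD after fit) of some reference; (ii) assign
    every frame to its nearest reference; (iii) split frames into halves by
    time (odd counts: extra frame to the first half) and count references
    whose group is empty in either half (*lone references*).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if trajectory.n_frames < 4:
        raise ValueError("need at least 4 frames")
    if isinstance(selection, str):
        sel = select(trajectory.topology, (int(trajectory.topology.res_ids.min()),
                                           int(trajectory.topology.res_ids.max())),
                     atom_filter=selection)
    else:
        sel = np.asarray(selection)
    n = trajectory.n_frames
    half_split = (n + 1) // 2       # extra frame to the first half
    reports = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        uncovered = np.arange(n)
        refs: list[int] = []
        dist_to_refs = np.full((0, n), np.inf)
        while len(uncovered):
            pick = int(rng.choice(uncovered))
            refs.append(pick)
            d = np.array([
                pairwise_rmsd(trajectory.frames[f], trajectory.frames[pick], sel)
                for f in range(n)
            ])
            dist_to_refs = np.vstack([dist_to_refs, d])
            uncovered = np.flatnonzero(dist_to_refs.min(axis=0) > cutoff)
        assignments = np.argmin(dist_to_refs, axis=0)
        lone = 0
        for r in range(len(refs)):
            members = np.flatnonzero(assignments == r)
            in_first = np.any(members < half_split)
            in_second = np.any(members >= half_split)
            if not (in_first and in_second):
                lone += 1
        reports.append(SeedReport(
            seed=int(seed),
            n_references=len(refs),
            n_lone_references=lone,
            reference_frames=[int(r) for r in refs],
            assignments=assignments,
        ))
    return ConvergenceReport(cutoff=cutoff, seeds=[int(s) for s in seeds],
                             per_seed=reports)
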