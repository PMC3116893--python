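"""Elastic-network normal modes and per-mode statistics.

An anisotropic network model (ANM) replaces all-atom force-field normal
mode analysis: atoms within a cutoff are connected by uniform springs and
the (optionally mass-weighted) Hessian is diagonalized. The six zero modes
(rigid translations/rotations) are discarded and the lowest non-zero modes
are retained — by convention the 97 lowest, mirroring a ω < 20 cm⁻¹ style
cutoff in relative frequency units.

Per-mode statistics:

* **degree of collectivity** k of the motion over an atom subset of size n,
  the exponential-entropy measure
  ``k = (1/n)·exp(−Σ u_i² ln u_i²)`` with u_i² the per-atom squared
  amplitudes normalized to sum to 1 over the subset — k = 1/n when a single
  atom moves, k = 1 when all move equally;
* **fragment resultant displacement** d_F, the norm of the vector sum of
  the mode's atomic components over a fragment — large when the fragment
  moves coherently in one direction — normalized by the maximum over a
  pooled mode ensemble;
* **mode overlap**, the scalar product between eigenvectors of two mode
  sets (or PCA mode sets), and the RMSIP subspace similarity.

Mode-following conformer generation displaces the structure linearly along
a mode with an RMSD-amplitude convention: amplitude a yields a conformation
at all-atom RMSD |a| from the origin (default grid −4 Å … +4 Å, step 0.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .structio import StructureModel, Trajectory

_ZERO_TOL = 1e-8


class HessianError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Hessian and modes
# ---------------------------------------------------------------------------

def build_hessian(
    structure: StructureModel,
    selection=None,
    cutoff: float = 12.0,
    gamma: float = 1.0,
    mass_weighted: bool = False,
):
    """Anisotropic-network Hessian (3N×3N) for the selected atoms.

    Uniform spring constant ``gamma`` between every atom pair within
    ``cutoff`` Å. With ``mass_weighted`` the Hessian is transformed as
    M^(−1/2) H M^(−1/2). Atoms with no neighbor within the cutoff trigger a
    warning (they contribute extra zero modes); a network with no springs
    at all is an error.

    Returns ``(hessian, masses)`` where ``masses`` is the per-selected-atom
    mass vector (needed to un-weight eigenvectors later).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    idx = np.arange(structure.n_atoms) if selection is None else np.asarray(selection)
    coords = structure.coords[idx]
    masses = structure.masses[idx]
    n = len(coords)
    if n < 2:
        raise HessianError("need at least 2 atoms")
    # collinear / degenerate geometry is not rejected here: it shows up as
    # extra zero modes, which compute_modes refuses to drop silently

    diff = coords[:, None, :] - coords[None, :, :]
    dist2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(dist2, np.inf)
    contact = dist2 <= cutoff**2

    degree = contact.sum(axis=1)
    if np.all(degree == 0):
        raise HessianError("no atom pair within the cutoff: empty network")
    lonely = np.flatnonzero(degree == 0)
    if len(lonely):
        warnings.warn(
            f"{len(lonely)} atom(s) have no neighbor within {cutoff} Å "
            f"(selected-atom indices {lonely.tolist()}); extra zero modes "
            "will appear",
            stacklevel=2,
        )

    hessian = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(np.triu(contact, k=1))
    for i, j in zip(ii, jj):
        d = diff[i, j]
        block = -gamma * np.outer(d, d) / dist2[i, j]
        hessian[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
        hessian[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
        hessian[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        hessian[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block

    if mass_weighted:
        w = np.repeat(1.0 / np.sqrt(masses), 3)
        hessian = hessian * w[:, None] * w[None, :]
    return hessian, masses


@dataclass
class ModeSet:
    """Non-zero eigenmodes of an ENM Hessian, sorted by eigenvalue."""

    eigenvectors: np.ndarray    # (n_modes, 3N), orthonormal rows
    eigenvalues: np.ndarray     # (n_modes,), ascending, > 0
    n_atoms: int
    mass_weighted: bool
    n_zero_modes: int
    masses: np.ndarray | None = None    # per-atom, present when mass-weighted

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def frequencies(self) -> np.ndarray:
        """√eigenvalue, in arbitrary (relative cm⁻¹-like) units."""
        return np.sqrt(self.eigenvalues)

    def atom_amplitudes(self, mode: int) -> np.ndarray:
        """Per-atom squared amplitude u_i² (Σ over x,y,z components)."""
        v = self.eigenvectors[mode].reshape(-1, 3)
        return np.einsum("ij,ij->i", v, v)


def compute_modes(
    hessian: np.ndarray,
    n_modes: int | None = None,
    mass_weighted: bool = False,
    masses: np.ndarray | None = None,
    expected_zero_modes: int = 6,
) -> ModeSet:
    """Diagonalize a Hessian and return the lowest non-zero modes.

    The ``expected_zero_modes`` near-zero eigenvalues (6 rigid-body modes
    for a non-collinear 3-D structure) are discarded. If *more* eigenvalues
    are numerically zero — degenerate geometry or a disconnected spring
    network — an error is raised rather than silently dropping modes.
    """
    hessian = np.asarray(hessian)
    dim = hessian.shape[0]
    if dim % 3 or hessian.shape[1] != dim:
        raise ValueError("Hessian must be square with dimension 3N")
    evals, evecs = scipy.linalg.eigh(hessian)
    tol = _ZERO_TOL * max(evals[-1], 1.0)
    n_zero = int(np.sum(np.abs(evals) < tol))
    if n_zero > expected_zero_modes:
        raise HessianError(
            f"{n_zero} near-zero eigenvalues found (expected "
            f"{expected_zero_modes}): degenerate geometry or disconnected "
            "network"
        )
    nonzero_vals = evals[n_zero:]
    nonzero_vecs = evecs[:, n_zero:].T
    available = len(nonzero_vals)
    if n_modes is None:
        n_modes = min(97, available)
    if n_modes > available:
        raise ValueError(
            f"requested {n_modes} modes but only {available} non-zero modes exist"
        )
    return ModeSet(
        eigenvectors=np.ascontiguousarray(nonzero_vecs[:n_modes]),
        eigenvalues=nonzero_vals[:n_modes].copy(),
        n_atoms=dim // 3,
        mass_weighted=mass_weighted,
        n_zero_modes=n_zero,
        masses=np.asarray(masses) if masses is not None else None,
    )


def compute_enm_modes(
    structure: StructureModel,
    selection=None,
    cutoff: float = 12.0,
    gamma: float = 1.0,
    mass_weighted: bool = False,
    n_modes: int | None = 97,
) -> ModeSet:
    """Convenience: build the ENM Hessian and diagonalize in one call."""
    hessian, masses = build_hessian(
        structure, selection=selection, cutoff=cutoff, gamma=gamma,
        mass_weighted=mass_weighted,
    )
    if n_modes is not None:
        n_modes = min(n_modes, hessian.shape[0] - 6)
    return compute_modes(hessian, n_modes, mass_weighted=mass_weighted,
                         masses=masses)


# ---------------------------------------------------------------------------
# per-mode statistics
# ---------------------------------------------------------------------------

def collectivity(
    modes, subset=None, renormalize: bool = True
) -> np.ndarray:
    """Degree of collectivity k per mode over an atom subset of size n.

    ``k = (1/n)·exp(−Σ_{i∈subset} u_i² ln u_i²)`` with ``0·ln 0 := 0``.
    With ``renormalize`` (default) the u_i² are rescaled to sum to 1 over
    the subset, so 1/n ≤ k ≤ 1 exactly; without it, the u_i² keep their
    whole-structure normalization and k measures the subset's share of a
    globally normalized motion. Modes with zero amplitude on the subset get
    NaN (undefined, not zero).

    ``modes`` may be a ModeSet or a plain (n_modes, 3N) eigenvector array.
    """
    vecs = modes.eigenvectors if hasattr(modes, "eigenvectors") else np.asarray(modes)
    if vecs.ndim == 1:
        vecs = vecs[None, :]
    amps2 = np.einsum("mij,mij->mi", vecs.reshape(len(vecs), -1, 3),
                      vecs.reshape(len(vecs), -1, 3))
    if subset is not None:
        amps2 = amps2[:, np.asarray(subset)]
    n = amps2.shape[1]
    if n == 0:
        raise ValueError("subset is empty")
    total = amps2.sum(axis=1)
    k = np.full(len(vecs), np.nan)
    ok = total > 0
    u2 = amps2[ok]
    if renormalize:
        u2 = u2 / total[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(u2 > 0, u2 * np.log(u2), 0.0).sum(axis=1)
    k[ok] = np.exp(-ent) / n
    return k


def fragment_displacement(modes, fragment) -> np.ndarray:
    """Raw resultant displacement d_F per mode over fragment atom indices M.

    d_F = ‖ Σ_{i∈M} (a_xi, a_yi, a_zi) ‖ — the norm of the vector sum of
    the mode's per-atom components, i.e. coherent net motion of the
    fragment (antisymmetric motions cancel to zero).
    """
    fragment = np.asarray(fragment)
    if len(fragment) == 0:
        raise ValueError("fragment is empty")
    vecs = modes.eigenvectors if hasattr(modes, "eigenvectors") else np.asarray(modes)
    if vecs.ndim == 1:
        vecs = vecs[None, :]
    per_atom = vecs.reshape(len(vecs), -1, 3)[:, fragment, :]
    resultant = per_atom.sum(axis=1)
    return np.linalg.norm(resultant, axis=1)


def normalize_pooled(raw_values: list[np.ndarray]):
    """Max-normalize fragment displacements over a pooled mode ensemble.

    Returns ``(normalized_list, (pool_index, mode_index))`` of the maximum;
    ties on the maximum are broken by lower (pool, mode) index. Exactly one
    pooled mode attains 1.0.
    """
    if not raw_values or all(len(r) == 0 for r in raw_values):
        raise ValueError("empty pooled mode ensemble")
    pooled = np.concatenate(raw_values)
    flat_arg = int(np.argmax(pooled))     # argmax takes the first on ties
    maximum = pooled[flat_arg]
    if maximum <= 0:
        raise ValueError("all pooled displacements are zero")
    offsets = np.cumsum([0] + [len(r) for r in raw_values])
    pool_idx = int(np.searchsorted(offsets, flat_arg, side="right") - 1)
    mode_idx = flat_arg - offsets[pool_idx]
    return [r / maximum for r in raw_values], (pool_idx, int(mode_idx))


def pooled_mode_metrics(
    modesets: list,
    subset,
    fragments: dict[str, np.ndarray],
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Collectivity and fragment displacements over a pooled mode ensemble.

    One row per (conformer, mode); normalized d_F and dense ranks (1 =
    largest) are computed within the pool, mirroring the treatment of the
    97 lowest modes pooled over several representative conformations.
    """
    if labels is None:
        labels = [f"conf{i}" for i in range(len(modesets))]
    rows = []
    k_all = [collectivity(ms, subset=subset) for ms in modesets]
    raw = {
        name: [fragment_displacement(ms, frag) for ms in modesets]
        for name, frag in fragments.items()
    }
    norm = {name: normalize_pooled(vals)[0] for name, vals in raw.items()}
    for s, (ms, label) in enumerate(zip(modesets, labels)):
        for m in range(ms.n_modes):
            row = {
                "conformer": label,
                "mode_index": m + 1,
                "eigenvalue": ms.eigenvalues[m],
                "k_subset": k_all[s][m],
            }
            for name in fragments:
                row[f"d_raw_{name}"] = raw[name][s][m]
                row[f"d_norm_{name}"] = norm[name][s][m]
            rows.append(row)
    table = pd.DataFrame(rows)
    table["rank_k"] = (
        table["k_subset"].rank(ascending=False, method="first").astype(int)
    )
    for name in fragments:
        table[f"rank_d_{name}"] = (
            table[f"d_norm_{name}"].rank(ascending=False, method="first").astype(int)
        )
    return table


def mode_overlap(modes_a, modes_b) -> np.ndarray:
    """Pairwise scalar products between two sets of (PCA or NMA) eigenvectors."""
    a = modes_a.eigenvectors if hasattr(modes_a, "eigenvectors") else np.asarray(modes_a)
    b = modes_b.eigenvectors if hasattr(modes_b, "eigenvectors") else np.asarray(modes_b)
    if a.shape[-1] != b.shape[-1]:
        raise ValueError(
            f"eigenvector dimensions differ: {a.shape[-1]} vs {b.shape[-1]}"
        )
    return a @ b.T


def rmsip(modes_a, modes_b) -> float:
    """Root-mean-square inner product between two mode subspaces."""
    o = mode_overlap(modes_a, modes_b)
    return float(np.sqrt(np.sum(o**2) / o.shape[0]))


# ---------------------------------------------------------------------------
# mode-following displacement
# ---------------------------------------------------------------------------

def default_amplitude_grid() -> np.ndarray:
    """−4 Å to +4 Å in steps of 0.1 Å (81 amplitudes)."""
    return np.round(np.arange(-40, 41) * 0.1, 10)


def displace_along_mode(
    structure: StructureModel,
    modes,
    mode_index: int = 0,
    amplitudes=None,
    direction: np.ndarray | None = None,
) -> Trajectory:
    """Linearly displace a structure along a mode, amplitude = RMSD in Å.

    The mode eigenvector is un-mass-weighted if needed, renormalized and
    scaled so the conformation at amplitude a sits at all-atom RMSD |a|
    from the input. ``direction`` may supply an explicit 3N displacement
    direction instead of a ModeSet entry. The trajectory's ``times`` carry
    the amplitude grid.
    """
    if direction is None:
        v = modes.eigenvectors[mode_index].copy()
        if getattr(modes, "mass_weighted", False):
            if modes.masses is None:
                raise ValueError("mass-weighted ModeSet lacks masses")
            v = v.reshape(-1, 3) / np.sqrt(modes.masses)[:, None]
            v = v.ravel()
    else:
        v = np.asarray(direction, dtype=float).ravel()
    if v.shape[0] != 3 * structure.n_atoms:
        raise ValueError("mode dimension does not match the structure")
    amplitudes = (
        default_amplitude_grid() if amplitudes is None
        else np.asarray(amplitudes, dtype=float)
    )
    if not np.all(np.isfinite(amplitudes)):
        raise ValueError("non-finite amplitude")
    v = v / np.linalg.norm(v)
    # unit 3N vector → per-frame RMSD of a·v is |a|/√N; rescale so RMSD = |a|
    step = v.reshape(-1, 3) * np.sqrt(structure.n_atoms)
    frames = structure.coords[None, :, :] + amplitudes[:, None, None] * step[None, :, :]
    return Trajectory(
        topology=structure,
        frames=frames,
        times=amplitudes.astype(float),
        metadata={"amplitudes": amplitudes, "mode_index": mode_index},
    )
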