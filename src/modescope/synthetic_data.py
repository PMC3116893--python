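"""Ground-truth-bearing synthetic inputs.

Because real kinase MD trajectories and force-field energy outputs are not
bundled, every downstream stage is exercised on constructions whose
statistical or geometric truth is known exactly:

* pseudo-helical Cα chains (ENM substrates),
* ideal α-helix backbones (H-bond geometry fixtures),
* Gaussian conformational ensembles drawn from an elastic-network
  covariance (stand-in for equilibrium MD sampling),
* two-state trajectories with controllable inter-state separation
  (convergence-analysis fixtures),
* stationary AR(1) scalar series with closed-form standard error of the
  mean (oracle for autocorrelation-aware error estimates),
* spherical-shell cavity structures with a mouth of known aperture
  (pocket-detection fixtures).

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import numpy as np

from .structio import StructureModel, Trajectory, build_model


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# chains and helices
# ---------------------------------------------------------------------------

def make_toy_chain(n_residues: int, seed: int = 0) -> StructureModel:
    """Cα-only pseudo-helical chain with consecutive Cα-Cα distance 3.8 Å.

    Atoms lie on a regular helix (radius 2.3 Å, 100°/residue) whose rise is
    chosen so the chord length is exactly 3.8 Å, plus a tiny seeded jitter
    (σ = 0.002 Å) so distinct seeds give distinct, non-degenerate geometry.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues for a non-collinear chain")
    rng = _rng(seed)
    radius, theta = 2.3, np.deg2rad(100.0)
    chord = 2.0 * radius * np.sin(theta / 2.0)
    rise = np.sqrt(3.8**2 - chord**2)
    i = np.arange(n_residues)
    coords = np.column_stack([
        radius * np.cos(i * theta),
        radius * np.sin(i * theta),
        rise * i,
    ])
    coords = coords + rng.normal(scale=0.002, size=coords.shape)
    return build_model(
        atom_names=["CA"] * n_residues,
        res_ids=np.arange(1, n_residues + 1),
        coords=coords,
        elements=["C"] * n_residues,
        res_names=["ALA"] * n_residues,
    )


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d given chain a-b-c, bond |c-d|, angle b-c-d, torsion a-b-c-d."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(torsion_deg)
    w = c - b
    w = w / np.linalg.norm(w)
    u = b - a
    n = np.cross(u, w)
    n = n / np.linalg.norm(n)
    m = np.cross(n, w)
    d_local = bond * np.array([
        -np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)
    ])
    return c + d_local[0] * w + d_local[1] * m + d_local[2] * n


def make_ideal_helix(n_residues: int) -> StructureModel:
    """Ideal α-helix backbone (N, H, CA, C, O per residue).

    Built from canonical internal coordinates (φ = −57°, ψ = −47°,
    ω = 180°; standard backbone bond lengths/angles), which yields the
    α-helical rise of ~1.5 Å and ~100°/residue turn and places the
    O(i)···H-N(i+4) hydrogen bonds of the helix.
    """
    if n_residues < 6:
        raise ValueError("need at least 6 residues for an α-helix fixture")
    phi, psi, omega = -57.0, -47.0, 180.0
    b_NCa, b_CaC, b_CN, b_CO, b_NH = 1.458, 1.525, 1.329, 1.231, 1.010
    a_NCaC, a_CaCN, a_CNCa, a_CaCO, a_CNH = 111.2, 116.2, 121.7, 120.5, 119.0

    N = np.zeros((n_residues, 3))
    H = np.zeros((n_residues, 3))
    CA = np.zeros((n_residues, 3))
    C = np.zeros((n_residues, 3))
    O = np.zeros((n_residues, 3))

    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (b_NCa, 0.0, 0.0)
    ang = np.deg2rad(180.0 - a_NCaC)
    C[0] = CA[0] + b_CaC * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_residues):
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1], b_CN, a_CaCN, psi)
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i], b_NCa, a_CNCa, omega)
        C[i] = _nerf(C[i - 1], N[i], CA[i], b_CaC, a_NCaC, phi)
    for i in range(n_residues):
        # carbonyl O in the peptide plane, anti to the next N
        O[i] = _nerf(N[i], CA[i], C[i], b_CO, a_CaCO, psi + 180.0)
        if i > 0:
            # amide H anti to the preceding carbonyl O across the C-N bond
            H[i] = _nerf(O[i - 1], C[i - 1], N[i], b_NH, a_CNH, 180.0)
    # first residue has no preceding peptide plane; place H in-plane
    H[0] = _nerf(C[0], CA[0], N[0], b_NH, a_CNH, 180.0)

    names, elements, res_ids, coords = [], [], [], []
    for i in range(n_residues):
        for name, elem, xyz in (
            ("N", "N", N[i]), ("H", "H", H[i]), ("CA", "C", CA[i]),
            ("C", "C", C[i]), ("O", "O", O[i]),
        ):
            names.append(name)
            elements.append(elem)
            res_ids.append(i + 1)
            coords.append(xyz)
    return build_model(
        atom_names=names,
        res_ids=np.array(res_ids),
        coords=np.array(coords),
        elements=elements,
        res_names=["ALA"] * len(names),
    )


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def sample_enm_ensemble(
    structure: StructureModel,
    modes,
    scale: float,
    n_frames: int,
    seed: int = 0,
    mode_indices=None,
) -> Trajectory:
    """Draw frames from the Gaussian the elastic network defines.

    Displacements are sums over the non-zero modes with per-mode variance
    ``scale / eigenvalue``, so the exact atom-displacement covariance is
    ``scale ×`` the Hessian pseudo-inverse. Rigid-body modes are excluded by
    construction (only non-zero modes live in a ModeSet), hence no net drift.
    ``mode_indices`` optionally restricts sampling to a subset of modes.

    For a mass-weighted ModeSet the mass-weighted displacement is mapped
    back to Cartesian coordinates per atom.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = _rng(seed)
    vecs = modes.eigenvectors          # (n_modes, 3N), orthonormal
    vals = modes.eigenvalues
    if mode_indices is not None:
        vecs = vecs[list(mode_indices)]
        vals = vals[list(mode_indices)]
    n_modes = len(vals)
    sd = np.sqrt(scale / vals)                        # (n_modes,)
    z = rng.standard_normal((n_frames, n_modes))
    disp = (z * sd) @ vecs                            # (F, 3N)
    if modes.mass_weighted:
        inv_sqrt_m = np.repeat(1.0 / np.sqrt(structure.masses), 3)
        disp = disp * inv_sqrt_m
    frames = structure.coords[None, :, :] + disp.reshape(n_frames, -1, 3)
    return Trajectory(
        topology=structure,
        frames=frames,
        times=np.arange(1.0, n_frames + 1.0),
        metadata={"generator": "enm_gaussian", "scale": scale, "seed": seed},
    )


def make_two_state_trajectory(
    struct_a: StructureModel,
    struct_b: StructureModel,
    n_frames: int,
    layout: str = "blocked",
    jitter: float = 0.0,
    seed: int = 0,
) -> Trajectory:
    """Trajectory hopping between two conformations A and B.

    ``blocked``: first half samples near A, second half near B — the
    signature of an unconverged simulation. ``shuffled``: states randomly
    interleaved — a converged-looking ensemble with the same marginal
    distribution. ``jitter`` is a per-coordinate Gaussian σ in Å.
    """
    if struct_a.n_atoms != struct_b.n_atoms:
        raise ValueError("the two states must share a topology")
    if n_frames % 2 != 0:
        raise ValueError("n_frames must be even (half per state)")
    if layout not in ("blocked", "shuffled"):
        raise ValueError("layout must be 'blocked' or 'shuffled'")
    rng = _rng(seed)
    half = n_frames // 2
    labels = np.array([0] * half + [1] * half)
    if layout == "shuffled":
        labels = rng.permutation(labels)
    frames = np.empty((n_frames, struct_a.n_atoms, 3))
    for f, lab in enumerate(labels):
        base = struct_a.coords if lab == 0 else struct_b.coords
        noise = rng.normal(scale=jitter, size=base.shape) if jitter > 0 else 0.0
        frames[f] = base + noise
    return Trajectory(
        topology=struct_a,
        frames=frames,
        times=np.arange(1.0, n_frames + 1.0),
        metadata={"generator": "two_state", "layout": layout,
                  "labels": labels, "seed": seed},
    )


def make_deformed_state(
    structure: StructureModel, rmsd: float, seed: int = 0
) -> StructureModel:
    """Internally deformed copy at a given best-fit RMSD from the input.

    A random per-atom perturbation is centered and rescaled iteratively so
    the post-superposition RMSD equals ``rmsd`` (rigid-body translation
    alone would be removed by fitting and is useless as a second state).
    """
    from .ensemble_stats import pairwise_rmsd

    if rmsd <= 0:
        raise ValueError("rmsd must be positive")
    rng = _rng(seed)
    pert = rng.normal(size=structure.coords.shape)
    pert -= pert.mean(axis=0)
    coords = structure.coords + pert
    for _ in range(4):
        current = pairwise_rmsd(coords, structure.coords)
        pert *= rmsd / current
        coords = structure.coords + pert
    return structure.with_coords(coords)


# ---------------------------------------------------------------------------
# scalar series
# ---------------------------------------------------------------------------

def make_ar1_series(
    mean: float, sigma: float, phi: float, n: int, seed: int = 0
) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sigma``.

    x_t = mean + phi·(x_{t-1} − mean) + ε_t with ε ~ N(0, σ²(1−φ²)), so the
    marginal sd is exactly σ and the true standard error of the sample mean
    is (σ/√n)·√((1+φ)/(1−φ)) — see :func:`ar1_standard_error`.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if not -1.0 < phi < 1.0:
        raise ValueError("phi must lie strictly inside (-1, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    if sigma == 0:
        return np.full(n, float(mean))
    x = np.empty(n)
    x[0] = rng.normal(scale=sigma)
    innov_sd = sigma * np.sqrt(1.0 - phi**2)
    eps = rng.normal(scale=innov_sd, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return mean + x


def ar1_standard_error(sigma: float, phi: float, n: int) -> float:
    """Closed-form large-n standard error of the mean of an AR(1) series."""
    return (sigma / np.sqrt(n)) * np.sqrt((1.0 + phi) / (1.0 - phi))


# ---------------------------------------------------------------------------
# cavities
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-angle spiral)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def make_cavity_structure(
    shell_radius: float = 8.0,
    aperture_deg: float = 40.0,
    n_atoms: int = 200,
    seed: int = 0,
    center=(0.0, 0.0, 0.0),
    mouth_axis=(0.0, 0.0, 1.0),
) -> StructureModel:
    """Hollow atom shell with a mouth: a cavity whose center is known.

    Atoms sit quasi-uniformly on a sphere of ``shell_radius`` (±0.05 Å
    seeded radial jitter) with a spherical cap of half-angle
    ``aperture_deg`` around ``mouth_axis`` removed. The cavity center is
    ``center`` by construction — the ground truth for pocket detection.
    """
    if not 0 < aperture_deg < 120:
        raise ValueError("aperture must be in (0, 120) degrees")
    rng = _rng(seed)
    cap_fraction = (1.0 - np.cos(np.deg2rad(aperture_deg))) / 2.0
    n_total = int(np.ceil(n_atoms / (1.0 - cap_fraction))) + 4
    pts = _fibonacci_sphere(n_total)
    axis = np.asarray(mouth_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    keep = pts @ axis < np.cos(np.deg2rad(aperture_deg))
    pts = pts[keep][:n_atoms]
    if len(pts) < 20:
        raise ValueError(
            f"parameters yield only {len(pts)} atoms (< 20); enlarge n_atoms"
        )
    radii = shell_radius + rng.uniform(-0.05, 0.05, size=len(pts))
    coords = pts * radii[:, None] + np.asarray(center, dtype=float)
    n = len(coords)
    return build_model(
        atom_names=["C"] * n,
        res_ids=np.arange(1, n + 1),
        coords=coords,
        elements=["C"] * n,
        res_names=["SHL"] * n,
    )


def make_double_cavity(
    shell_radius: float = 8.0,
    aperture_deg: float = 55.0,
    n_atoms_each: int = 350,
    gap: float = 1.0,
    neck_ring_radius: float = 3.0,
    n_ring: int = 24,
    seed: int = 0,
):
    """Two cavity shells whose mouths face each other across a narrow neck.

    The neck is an atom ring at the midplane whose radius is small enough
    that probe-inflated spheres seal it: grid points inside each chamber
    form two separate clusters that nevertheless approach each other across
    the neck. Returns ``(model, center_a, center_b)`` with the construction
    centers as ground truth.
    """
    offset = shell_radius + gap / 2.0
    center_a = np.array([0.0, 0.0, -offset])
    center_b = np.array([0.0, 0.0, +offset])
    shell_a = make_cavity_structure(
        shell_radius, aperture_deg, n_atoms_each, seed=seed,
        center=center_a, mouth_axis=(0, 0, 1),
    )
    shell_b = make_cavity_structure(
        shell_radius, aperture_deg, n_atoms_each, seed=seed + 1,
        center=center_b, mouth_axis=(0, 0, -1),
    )
    angles = 2.0 * np.pi * np.arange(n_ring) / n_ring
    ring = np.column_stack([
        neck_ring_radius * np.cos(angles),
        neck_ring_radius * np.sin(angles),
        np.zeros(n_ring),
    ])
    coords = np.vstack([shell_a.coords, shell_b.coords, ring])
    n = len(coords)
    model = build_model(
        atom_names=["C"] * n,
        res_ids=np.arange(1, n + 1),
        coords=coords,
        elements=["C"] * n,
        res_names=["SHL"] * n,
    )
    return model, center_a, center_b
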