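# Methods

## Scope and design

modescope implements the analysis layer of a kinase conformational-
dynamics study: normal-mode statistics, ensemble statistics, contact
occupancy, free-energy bookkeeping and pocket detection. It deliberately
does **not** produce the physics inputs — MD sampling, force-field
energies, GB solvation, normal-mode entropies — those enter as
multi-model PDB files and per-frame component tables. Everything the
package computes is therefore checkable against synthetic inputs whose
statistical or geometric truth is known exactly, and the test suite is
built that way.

## Structures, regions, selections

Structures are flat atom tables (coordinates in Å, author-assigned
1-based residue numbers, closed residue intervals). The default region
map carries the KIT cytoplasmic-region conventions (JM-Proximal 547–552,
JM-Buried 553–559, JM-Switch 560–570, JM-Zipper 571–581, JMR 547–581,
P-loop 596–601, C-helix 631–647, A-loop 810–835); any map can be
supplied as `label = start-end` lines. Van der Waals radii and masses
come from a bundled element table; apolar atoms are carbons/sulfurs
except the backbone carbonyl carbon (a name-based heuristic — side-chain
carbons bonded to N/O are still counted apolar, which slightly widens
hydrophobic maps). Alternate locations resolve to highest occupancy;
insertion codes are rejected so parsing is deterministic.

## Elastic network normal modes

All-atom force-field NMA is replaced by an anisotropic elastic network:
uniform springs (γ = 1) between atoms within a 12 Å cutoff, optional
mass weighting (M<sup>−1/2</sup> H M<sup>−1/2</sup>). The six rigid-body
modes are discarded; if *more* eigenvalues are numerically zero
(collinear geometry, disconnected network) the computation refuses to
drop them silently. The 97 lowest non-zero modes are kept by default —
the ENM analogue of a low-frequency cutoff; frequencies are reported as
√eigenvalue in relative units, so no absolute cm⁻¹ scale is claimed.

Per-mode statistics:

* Degree of collectivity k = (1/n)·exp(−Σ u_i² ln u_i²) with 0·ln 0 := 0.
  The squared amplitudes are renormalized over the analysis subset by
  default, which makes the bounds 1/n ≤ k ≤ 1 exact for subset analyses;
  the whole-structure normalization (where k measures the subset's share
  of global motion) is available via `renormalize=False`. Modes with zero
  amplitude on the subset yield NaN, never 0.
* Fragment resultant displacement d_F = ‖Σ_{i∈M} **a**_i‖. Reported raw
  and max-normalized over a *pooled* ensemble of modes (e.g. 4 × 97
  modes from four representative conformations), ties on the maximum
  broken by lower (conformer, mode) index, so exactly one pooled mode
  scores 1.00; dense first-occurrence ranks accompany both metrics.
* Overlap = scalar product between eigenvectors; RMSIP for subspaces.

Mode-following displacement is linear, with an RMSD-amplitude
convention: the conformer at amplitude a lies at all-atom RMSD |a| from
the input (default grid −4…+4 Å, step 0.1, 81 conformers). A restrained
minimization along the mode would need a force field, which is out of
scope; the linear contract is exactly testable and suffices for
grid-based pocket scanning on displaced conformers.

## Ensemble statistics

Superposition is a weighted Kabsch fit restricted to proper rotations
(mirror solutions rejected via the determinant sign). Fluctuation
tensors and PCA first superpose all frames onto an iteratively fitted
average (fit → average → refit, 2 fixed iterations — the average moves
negligibly after that and a fixed count keeps runs deterministic), then
diagonalize the 3N×3N positional covariance. `n_modes_for_variance`
answers "how many PCA modes cover fraction f of the fluctuations"
(default f = 0.9).

The convergence analysis picks reference frames uniformly at random from
the not-yet-covered set until every frame lies within r (Cα RMSD) of a
reference, assigns each frame to its *nearest* reference (deterministic,
unlike first-within-r), splits the trajectory into halves at the frame-
index midpoint (odd counts: extra frame to the first half), and counts
references with an empty half — *lone references*. Five seeds by
default. On synthetic data the verdict contrast is sharp: blocked
two-state trajectories give lone references for every seed, shuffled
ones give none.

## Contacts, occupancy, SASA

Hydrogen bonds use geometric criteria with explicit hydrogens —
H···A ≤ 2.5 Å, D···A ≤ 3.5 Å, ∠DHA ≥ 120°; the source analysis cites
geometric assignment without printing thresholds, so these standard,
HBPLUS-compatible values are defaults and every threshold is a
parameter. Structures without hydrogens fall back to D···A distance plus
a 90° cone around the donor's outward direction, with a logged notice.
Hydrophobic contacts are apolar heavy-atom pairs ≤ 4.5 Å across
residues. Occupancy maps count, per residue pair across two disjoint
regions, the fraction of productive frames with ≥ 1 qualifying event;
pairs below the threshold (default 15%) are dropped from the filtered
table but kept in the raw one. Productive time excludes a per-replica
relaxation period (e.g. two 50-ns replicas − 2 ns each → 96 ns pooled).

SASA is Shrake-Rupley quadrature (default probe 1.5 Å, 960 golden-spiral
points per atom; isolated-sphere error < 1%), summed per residue.

## Free-energy bookkeeping

Per-frame tables with columns `time_ps E_int E_ele E_vdw G_gb G_sa
TS_trans TS_rot TS_vib` are combined as E_gas = E_int + E_ele + E_vdw,
H = E_gas + G_gb + G_sa, TS = ΣTS, G = H − TS (kcal/mol). Entropy
columns may be sparse (evaluated on a frame subset); they are averaged
over their own grid and G's error then combines H and TS errors in
quadrature.

Errors on means of correlated series use the Straatsma estimator
error² = (var/T)(1 + 2Σ_{k≥1} ρ_k). The autocorrelation sum is truncated
at the first non-positive sample ρ_k (initial-positive-sequence rule — a
standard, conservative estimator choice; the truncated sum is reported
as the correlation length τ). Against the closed-form AR(1) oracle
(σ/√n)·√((1+φ)/(1−φ)) the estimate is within a few percent at n = 10⁵
for φ = 0 and φ = 0.9.

Stability changes are mutant − wild-type differences with quadrature
errors. Binding cycles take six legs (complex/receptor/ligand ×
wild-type/mutant), compute ΔG_bind = G_complex − G_receptor − G_ligand
per form and ΔΔX = ΔX_bind(mut) − ΔX_bind(wt), decomposing ΔΔH into
gas-phase, polar- and nonpolar-solvation parts. Single-frame legs
(single-point estimates) carry zero statistical error. Sign convention:
more negative G = more stable; ΔΔG < 0 means the ligand binds more
tightly in the wild-type.

## Pocket detection and paths

A LIGSITE-style scan replaces alpha-sphere detection: cubic lattice
(spacing 0.8 Å), protein occupancy = within vdw + 1.4 Å probe of any
atom, burial tested along 7 axes (x, y, z, 4 cube diagonals; protein on
*both* sides counts), threshold 5 of 7, 26-connectivity clustering,
clusters < 30 points discarded, volume = points × spacing³. Pockets
whose point sets approach within a merge distance (default 2 × spacing)
are adjacent; a path between two atom selections exists when a connected
component of the adjacency graph touches both (contact = any pocket
point within 4.5 Å of the selection).

Ground truth comes from shell fixtures: a spherical cage of atoms
(radius 8 Å, 40° mouth) must yield exactly one pocket centered at the
construction origin — observed centroid error ≈ 0.2 Å. The two-chamber
fixture fuses two shells mouth-to-mouth across an atom ring
(ring radius 3.05 Å) that the probe-inflated spheres seal; the two
chamber clusters end ≈ 4 Å apart across that seal (stable across seeds,
a consequence of the 3.1 Å blocking radius of a ring carbon), so the
path analysis across the neck passes `merge_distance = 5 Å` explicitly
rather than the 2 × spacing default. Volume is approximately invariant
under rotation (< 15% change; exact up to discretization for 90°
rotations).

## Synthetic generators — what they emulate, and what not

* `make_toy_chain` — pseudo-helical Cα chains with exact 3.8 Å virtual
  bonds: a geometry substrate, not a protein model.
* `make_ideal_helix` — backbone from canonical internal coordinates
  (φ = −57°, ψ = −47°, ω = 180°), giving the O(i)···N(i+4) ≈ 3.1 Å
  α-helical hydrogen bonds used to validate the H-bond detector. Note
  that O(i)–N(i+1) is covalently constrained to ≈ 2.25 Å through the
  carbonyl carbon; the meaningful negative control is that the *detector*
  reports no i→i+1 bond (the amide H points anti to the preceding
  carbonyl, failing the angle criterion).
* `sample_enm_ensemble` — Gaussian sampling along non-zero ENM modes
  with per-mode variance scale/λ: the exact displacement covariance is
  scale × H⁺, so PCA and fluctuation stages have an analytic target.
  Rigid-body modes are excluded so superposition is not confounded.
  This emulates the stationary distribution of equilibrium dynamics
  only — no kinetics, no anharmonicity, no solvent.
* `make_two_state_trajectory` / `make_deformed_state` — hopping between
  two internally deformed conformations (a pure translation would be
  removed by fitting); blocked vs shuffled layouts give the
  non-converged/converged contrast with identical marginals.
* `make_ar1_series` — stationary AR(1) with marginal sd σ: the exact
  standard error of the mean is known, making the error model testable.
  Real MM-GBSA series have heavier tails and slower mixing; passing the
  AR(1) calibration shows estimator correctness, not universality.
* `make_cavity_structure` / `make_double_cavity` — atom shells with
  known cavity centers; these test geometric truth, not chemistry.

Passing on these fixtures demonstrates algorithmic correctness and exact
bookkeeping. It does not demonstrate that any biological conclusion
about a real kinase would be recovered — that depends on the MD and
energy inputs, which are out of scope.

## Problem sizes and numerical choices

The study drivers use a 60-residue chain, 200-frame ensembles, 2400-row
energy tables and 200-atom cavity shells — sizes at which every stage
completes in seconds while leaving the statistics sharp (covariance
recovery < 5% Frobenius error at 5000 frames; Straatsma within 20% of
the AR(1) oracle at 10⁵ points). Zero-eigenvalue tolerance is 1e-8
relative to the largest eigenvalue; eigensolvers are LAPACK `eigh` on
dense matrices (3N ≤ a few hundred). All randomness flows through
`numpy.random.default_rng` seeds; the pipeline derives per-stage seeds
from one global seed by hashing, and every generator is a pure function
of (parameters, seed).

## Known limitations

* The ENM reproduces low-frequency mode *geometry*, not force-field
  frequencies; collectivity/displacement values on real proteins will
  differ numerically from all-atom NMA even though the statistics'
  definitions are identical.
* Whether collectivity should be normalized over the analysis subset or
  the whole structure is a genuine convention choice; subset
  normalization is the default because it makes the stated bounds exact,
  and the alternative is a flag.
* The hydrogen-free H-bond fallback is permissive (no angle at the
  acceptor); add hydrogens for serious use.
* Pocket volumes are grid-resolution limited (one cell ≈ 0.5 Å³ at the
  default spacing) and the buriedness criterion is direction-discretized;
  only qualitative pocket reasoning should be built on them.
* mmCIF and binary trajectory formats are not read; multi-model PDB is
  the interchange format.
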