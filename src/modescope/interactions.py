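"""Geometric contact detection, trajectory occupancy maps, and SASA.

Hydrogen bonds D-H···A are assigned by geometric criteria (defaults
H···A ≤ 2.5 Å, D···A ≤ 3.5 Å, ∠DHA ≥ 120°; HBPLUS-compatible ranges);
hydrophobic contacts are apolar heavy-atom pairs within 4.5 Å. Occupancy
maps report, per residue pair, the fraction of productive frames in which
at least one qualifying contact exists, keeping pairs at or above a
threshold (default 15%). Solvent-accessible surface areas use Shrake-
Rupley quadrature (default probe 1.5 Å, 960 points per atom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structio import StructureModel, Trajectory

logger = logging.getLogger(__name__)

HBOND_DEFAULTS = {"d_ha_max": 2.5, "d_da_max": 3.5, "angle_dha_min": 120.0}
HYDROPHOBIC_D_MAX = 4.5
_COVALENT_H_CUTOFF = 1.3   # Å, H attached to its donor heavy atom


@dataclass
class ContactEvent:
    frame: int
    type: str                   # 'hbond' | 'hydrophobic'
    atom_i: int                 # donor heavy atom / first apolar atom index
    atom_j: int                 # acceptor / second apolar atom index
    res_i: int
    res_j: int
    distance: float             # H···A for hbond, atom-atom otherwise (Å)
    angle: float | None = None  # ∠DHA in degrees, hbond only


def _donors_with_h(model: StructureModel, coords: np.ndarray):
    """(donor_index, hydrogen_index) pairs: H within 1.3 Å of an N/O."""
    h_idx = np.flatnonzero(model.elements == "H")
    heavy_no = np.flatnonzero(np.isin(model.elements, ("N", "O")))
    pairs = []
    if len(h_idx) == 0 or len(heavy_no) == 0:
        return pairs
    tree = cKDTree(coords[heavy_no])
    dists, nearest = tree.query(coords[h_idx], k=1)
    for h, d, j in zip(h_idx, dists, nearest):
        if d <= _COVALENT_H_CUTOFF:
            pairs.append((int(heavy_no[j]), int(h)))
    return pairs


def detect_hbonds(
    model: StructureModel,
    coords: np.ndarray | None = None,
    d_ha_max: float = HBOND_DEFAULTS["d_ha_max"],
    d_da_max: float = HBOND_DEFAULTS["d_da_max"],
    angle_dha_min: float = HBOND_DEFAULTS["angle_dha_min"],
    frame: int = 0,
) -> list[ContactEvent]:
    """Detect D-H···A hydrogen bonds in one conformation.

    Donors are N/O atoms with a covalently attached hydrogen; acceptors
    are any N/O. All three criteria must hold. If the structure carries no
    hydrogens at all, detection falls back to a heavy-atom heuristic:
    D···A ≤ ``d_da_max`` with the acceptor inside a 90° cone around the
    donor's outward direction (a notice is logged).
    """
    coords = model.coords if coords is None else np.asarray(coords)
    acceptors = np.flatnonzero(np.isin(model.elements, ("N", "O")))
    if len(acceptors) == 0:
        return []
    donors = _donors_with_h(model, coords)
    events: list[ContactEvent] = []
    if donors:
        acc_tree = cKDTree(coords[acceptors])
        for d_idx, h_idx in donors:
            for a_pos in acc_tree.query_ball_point(coords[h_idx], d_ha_max):
                a_idx = int(acceptors[a_pos])
                if a_idx in (d_idx, h_idx):
                    continue
                d_ha = float(np.linalg.norm(coords[a_idx] - coords[h_idx]))
                d_da = float(np.linalg.norm(coords[a_idx] - coords[d_idx]))
                if d_da > d_da_max:
                    continue
                v1 = coords[d_idx] - coords[h_idx]
                v2 = coords[a_idx] - coords[h_idx]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle < angle_dha_min:
                    continue
                events.append(ContactEvent(
                    frame=frame, type="hbond", atom_i=d_idx, atom_j=a_idx,
                    res_i=int(model.res_ids[d_idx]),
                    res_j=int(model.res_ids[a_idx]),
                    distance=d_ha, angle=angle,
                ))
        return events

    # no hydrogens anywhere: heavy-atom fallback
    if np.any(model.elements == "H"):
        return events
    logger.warning(
        "structure has no hydrogens; falling back to donor-acceptor "
        "distance + 90-degree cone criterion"
    )
    heavy_no = acceptors
    tree = cKDTree(coords[heavy_no])
    heavy = np.flatnonzero(model.elements != "H")
    nbr_tree = cKDTree(coords[heavy])
    for d_pos, d_idx in enumerate(heavy_no):
        d_idx = int(d_idx)
        for a_pos in tree.query_ball_point(coords[d_idx], d_da_max):
            a_idx = int(heavy_no[a_pos])
            if a_idx <= d_idx:
                continue
            d_da = float(np.linalg.norm(coords[a_idx] - coords[d_idx]))
            # outward direction: away from the mean of covalent neighbors
            nbrs = [int(heavy[k]) for k in
                    nbr_tree.query_ball_point(coords[d_idx], 1.8)
                    if int(heavy[k]) != d_idx]
            if nbrs:
                outward = coords[d_idx] - coords[nbrs].mean(axis=0)
                nrm = np.linalg.norm(outward)
                if nrm > 1e-9:
                    cosang = np.dot(outward / nrm,
                                    (coords[a_idx] - coords[d_idx]) / d_da)
                    if cosang < 0.0:       # outside the 90° cone
                        continue
            events.append(ContactEvent(
                frame=frame, type="hbond", atom_i=d_idx, atom_j=a_idx,
                res_i=int(model.res_ids[d_idx]),
                res_j=int(model.res_ids[a_idx]),
                distance=d_da, angle=None,
            ))
    return events


def detect_hydrophobic(
    model: StructureModel,
    coords: np.ndarray | None = None,
    d_max: float = HYDROPHOBIC_D_MAX,
    frame: int = 0,
) -> list[ContactEvent]:
    """Apolar heavy-atom pairs within ``d_max`` Å, different residues only."""
    coords = model.coords if coords is None else np.asarray(coords)
    apolar = np.flatnonzero(model.apolar)
    events: list[ContactEvent] = []
    if len(apolar) < 2:
        return events
    tree = cKDTree(coords[apolar])
    for i_pos, j_pos in sorted(tree.query_pairs(d_max)):
        i, j = int(apolar[i_pos]), int(apolar[j_pos])
        if model.res_ids[i] == model.res_ids[j] and \
                model.chain_ids[i] == model.chain_ids[j]:
            continue
        events.append(ContactEvent(
            frame=frame, type="hydrophobic", atom_i=i, atom_j=j,
            res_i=int(model.res_ids[i]), res_j=int(model.res_ids[j]),
            distance=float(np.linalg.norm(coords[i] - coords[j])),
        ))
    return events


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

@dataclass
class OccupancyMap:
    """Residue-pair contact occupancies over the productive frames."""

    table: pd.DataFrame          # res_a, res_b, type, occupancy (filtered)
    raw: pd.DataFrame            # unfiltered occupancies
    threshold: float
    n_frames: int
    contact_type: str


def pooled_productive_time(replica_lengths_ns, relaxation_ns: float = 2.0) -> float:
    """Pooled productive simulation time: Σ (length − relaxation) per replica.

    This is the occupancy denominator; e.g. two 50-ns replicas with a 2-ns
    relaxation each pool to 96 ns.
    """
    lengths = np.asarray(replica_lengths_ns, dtype=float)
    if np.any(lengths <= relaxation_ns):
        raise ValueError("replica shorter than its relaxation period")
    return float(np.sum(lengths - relaxation_ns))


def productive_frames(trajectory: Trajectory, relaxation_ps: float) -> Trajectory:
    """Drop the initial relaxation period; keep frames with t > relaxation."""
    keep = trajectory.times > relaxation_ps
    if not np.any(keep):
        raise ValueError("no frames left after the relaxation period")
    return Trajectory(
        topology=trajectory.topology,
        frames=trajectory.frames[keep],
        times=trajectory.times[keep],
        metadata=dict(trajectory.metadata, relaxation_ps=relaxation_ps),
    )


def occupancy_map(
    trajectory: Trajectory,
    region_a,
    region_b,
    contact_type: str = "hbond",
    threshold: float = 0.15,
    **criteria,
) -> OccupancyMap:
    """Per-residue-pair contact occupancy between two disjoint regions.

    For every frame, contacts are detected and a residue pair (a in
    region_a, b in region_b) counts as present if at least one qualifying
    event links them. Occupancy = fraction of frames present; pairs below
    ``threshold`` are dropped from ``table`` (kept in ``raw``).
    """
    if trajectory.n_frames == 0:
        raise ValueError("trajectory has zero frames")
    topo = trajectory.topology
    res_a = set(topo.res_ids[np.asarray(region_a)].tolist())
    res_b = set(topo.res_ids[np.asarray(region_b)].tolist())
    if res_a & res_b:
        raise ValueError("regions must be disjoint at the residue level")
    detector = detect_hbonds if contact_type == "hbond" else detect_hydrophobic
    if contact_type not in ("hbond", "hydrophobic"):
        raise ValueError("contact_type must be 'hbond' or 'hydrophobic'")
    counts: dict[tuple[int, int], int] = {}
    for f in range(trajectory.n_frames):
        events = detector(topo, trajectory.frames[f], frame=f, **criteria)
        seen = set()
        for ev in events:
            pair = None
            if ev.res_i in res_a and ev.res_j in res_b:
                pair = (ev.res_i, ev.res_j)
            elif ev.res_j in res_a and ev.res_i in res_b:
                pair = (ev.res_j, ev.res_i)
            if pair is not None:
                seen.add(pair)
        for pair in seen:
            counts[pair] = counts.get(pair, 0) + 1
    rows = [
        {"res_a": a, "res_b": b, "type": contact_type,
         "occupancy": c / trajectory.n_frames}
        for (a, b), c in sorted(counts.items())
    ]
    raw = pd.DataFrame(rows, columns=["res_a", "res_b", "type", "occupancy"])
    table = raw[raw["occupancy"] >= threshold].reset_index(drop=True)
    return OccupancyMap(table=table, raw=raw, threshold=threshold,
                        n_frames=trajectory.n_frames, contact_type=contact_type)


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(
    model: StructureModel,
    coords: np.ndarray | None = None,
    probe_radius: float = 1.5,
    n_sphere_points: int = 960,
    heavy_only: bool = True,
):
    """Shrake-Rupley solvent-accessible surface area.

    Each atom's sphere of radius (vdw + probe) is sampled with a golden-
    spiral quadrature; points inside any neighbor's inflated sphere are
    occluded. Returns ``(atom_areas, per_residue)`` in Å² where
    ``per_residue`` is a DataFrame summing atoms by residue.
    """
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    coords = model.coords if coords is None else np.asarray(coords)
    active = np.flatnonzero(model.elements != "H") if heavy_only \
        else np.arange(model.n_atoms)
    radii = model.vdw_radii + probe_radius
    unit = _sphere_points(n_sphere_points)
    tree = cKDTree(coords[active])
    max_r = radii[active].max()
    atom_areas = np.zeros(model.n_atoms)
    for pos, i in enumerate(active):
        r_i = radii[i]
        pts = coords[i] + r_i * unit
        nbr_pos = tree.query_ball_point(coords[i], r_i + max_r)
        nbrs = [active[p] for p in nbr_pos if active[p] != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in nbrs:
            occluded = ((pts - coords[j]) ** 2).sum(axis=1) < radii[j] ** 2
            accessible &= ~occluded
            if not accessible.any():
                break
        atom_areas[i] = 4.0 * np.pi * r_i**2 * accessible.mean()
    per_res = pd.DataFrame({
        "res_id": model.res_ids,
        "res_name": model.res_names,
        "area": atom_areas,
    }).groupby(["res_id", "res_name"], as_index=False)["area"].sum()
    return atom_areas, per_res


def relative_sasa_change(per_res_a: pd.DataFrame, per_res_b: pd.DataFrame) -> pd.DataFrame:
    """Per-residue relative SASA change (b vs a), in percent."""
    merged = per_res_a.merge(per_res_b, on="res_id", suffixes=("_a", "_b"))
    merged["pct_change"] = 100.0 * (merged["area_b"] - merged["area_a"]) \
        / merged["area_a"].replace(0.0, np.nan)
    return merged[["res_id", "area_a", "area_b", "pct_change"]]
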