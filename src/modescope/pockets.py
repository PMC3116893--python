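"""Grid-based pocket detection and pocket-adjacency path analysis.

A LIGSITE-style buriedness scan replaces alpha-sphere methods: a cubic
lattice (default 0.8 Å spacing) covers the structure, grid points inside
any probe-inflated atom sphere (vdw + 1.4 Å) are protein, and each
remaining solvent point is tested for burial along 7 scan axes (x, y, z
and the four cube diagonals) — buried along an axis means protein occurs
on *both* sides. Points buried along at least ``burial_min`` axes are
clustered by 26-connectivity; clusters below ``min_points`` are dropped.
Pockets whose point sets approach within a merge distance (default
2 × spacing) are adjacent, and a "path of pockets" exists between two
atom selections (e.g. a vacated regulatory-segment site and the catalytic
site) when one connected component of the adjacency graph touches both.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .structio import StructureModel

PROBE_RADIUS = 1.4        # Å added to vdw radii for solvent exclusion

# scan axes: x, y, z and the four main cube diagonals
_SCAN_DIRECTIONS = np.array([
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1),
], dtype=int)


@dataclass
class Pocket:
    id: int
    points: np.ndarray       # (n, 3) Å
    centroid: np.ndarray     # (3,) Å
    volume: float            # Å³ = n_points × spacing³

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class PocketSet:
    pockets: list[Pocket]
    spacing: float
    adjacency: nx.Graph      # nodes = pocket ids

    def __len__(self) -> int:
        return len(self.pockets)

    @property
    def total_volume(self) -> float:
        return sum(p.volume for p in self.pockets)

    def by_id(self, pid: int) -> Pocket:
        for p in self.pockets:
            if p.id == pid:
                return p
        raise KeyError(pid)


def _shift(arr: np.ndarray, step: np.ndarray) -> np.ndarray:
    """Shift a 3-D boolean array by an integer step, zero-filled."""
    out = np.zeros_like(arr)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(step):
        if s > 0:
            src[ax] = slice(s, None)
            dst[ax] = slice(None, -s)
        elif s < 0:
            src[ax] = slice(None, s)
            dst[ax] = slice(-s, None)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _blocked_along(occupied: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """True where any occupied cell lies strictly ahead along ``direction``.

    Log-doubling reachability: after propagation, reach[p] = occupied
    anywhere at p + k·d, k ≥ 0; shifting once more makes it strict.
    """
    reach = occupied.copy()
    span = max(occupied.shape)
    step = direction.copy()
    total = 1
    while total < span:
        reach |= _shift(reach, step)
        step = step * 2
        total *= 2
    return _shift(reach, direction)


def detect_pockets(
    structure: StructureModel,
    spacing: float = 0.8,
    burial_min: int = 5,
    min_points: int = 30,
    probe_radius: float = PROBE_RADIUS,
    padding: float = 2.0,
    merge_distance: float | None = None,
) -> PocketSet:
    """Detect buried cavities on one conformation.

    ``burial_min`` of the 7 scan axes must see protein on both sides for a
    solvent grid point to count as pocket space. ``merge_distance`` sets
    the pocket-adjacency threshold (default 2 × spacing); chambers sealed
    from each other by a probe-inflated constriction sit farther apart
    than that, so path analyses across narrow necks pass a larger value
    commensurate with the constriction's sealing margin.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if not 1 <= burial_min <= 7:
        raise ValueError("burial_min must be within 1..7")
    if structure.n_atoms < 20:
        raise ValueError("need at least 20 atoms for pocket detection")
    coords = structure.coords
    radii = structure.vdw_radii + probe_radius
    lo = coords.min(axis=0) - radii.max() - padding
    hi = coords.max(axis=0) + radii.max() + padding
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    occupied = np.zeros(shape, dtype=bool)
    # mark protein-occupied cells atom by atom (exact per-atom radii)
    for xyz, r in zip(coords, radii):
        ijk_lo = np.maximum(np.floor((xyz - r - lo) / spacing).astype(int), 0)
        ijk_hi = np.minimum(np.ceil((xyz + r - lo) / spacing).astype(int) + 1,
                            shape)
        ranges = [np.arange(ijk_lo[a], ijk_hi[a]) for a in range(3)]
        gi, gj, gk = np.meshgrid(*ranges, indexing="ij")
        centers = lo + np.stack([gi, gj, gk], axis=-1) * spacing
        inside = ((centers - xyz) ** 2).sum(axis=-1) <= r**2
        occupied[gi[inside], gj[inside], gk[inside]] = True

    burial_count = np.zeros(shape, dtype=np.int8)
    for d in _SCAN_DIRECTIONS:
        ahead = _blocked_along(occupied, d)
        behind = _blocked_along(occupied, -d)
        burial_count += (ahead & behind).astype(np.int8)
    pocket_space = (~occupied) & (burial_count >= burial_min)

    labels, n_labels = ndimage.label(pocket_space, structure=np.ones((3, 3, 3)))
    pockets: list[Pocket] = []
    pid = 0
    for lab in range(1, n_labels + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) < min_points:
            continue
        pts = lo + idx * spacing
        pockets.append(Pocket(
            id=pid,
            points=pts,
            centroid=pts.mean(axis=0),
            volume=len(idx) * spacing**3,
        ))
        pid += 1
    graph = nx.Graph()
    graph.add_nodes_from(p.id for p in pockets)
    merge_dist = 2.0 * spacing if merge_distance is None else merge_distance
    for i in range(len(pockets)):
        tree = cKDTree(pockets[i].points)
        for j in range(i + 1, len(pockets)):
            dmin = tree.query(pockets[j].points, k=1)[0].min()
            if dmin <= merge_dist:
                graph.add_edge(pockets[i].id, pockets[j].id)
    return PocketSet(pockets=pockets, spacing=spacing, adjacency=graph)


@dataclass
class PathReport:
    path_exists: bool
    path_pockets: list[int]          # pocket ids in order, start → site
    labels: pd.DataFrame             # pocket_id, n_points, volume, touches_*


def pocket_path(
    pocket_set: PocketSet,
    structure: StructureModel,
    site_selection,
    start_selection,
    contact_dist: float = 4.5,
) -> PathReport:
    """Does a chain of adjacent pockets connect a start region to a site?

    Each pocket is labelled by contact (any pocket point within
    ``contact_dist`` of any atom of the selection) with the site and/or
    the start region; the report gives the shortest adjacency path from a
    start-touching pocket to a site-touching pocket, if one exists.
    """
    site_idx = np.asarray(site_selection)
    start_idx = np.asarray(start_selection)
    if len(site_idx) == 0:
        raise ValueError("site selection is empty")
    rows = []
    touches_site: list[int] = []
    touches_start: list[int] = []
    site_tree = cKDTree(structure.coords[site_idx])
    start_tree = cKDTree(structure.coords[start_idx]) if len(start_idx) else None
    for p in pocket_set.pockets:
        ts = bool((site_tree.query(p.points, k=1)[0] < contact_dist).any())
        tt = bool(start_tree is not None and
                  (start_tree.query(p.points, k=1)[0] < contact_dist).any())
        if ts:
            touches_site.append(p.id)
        if tt:
            touches_start.append(p.id)
        rows.append({"pocket_id": p.id, "n_points": p.n_points,
                     "volume_A3": p.volume, "touches_site": ts,
                     "touches_start": tt})
    labels = pd.DataFrame(
        rows, columns=["pocket_id", "n_points", "volume_A3",
                       "touches_site", "touches_start"]
    )
    best_path: list[int] | None = None
    for a in touches_start:
        for b in touches_site:
            try:
                path = nx.shortest_path(pocket_set.adjacency, a, b)
            except nx.NetworkXNoPath:
                continue
            if best_path is None or len(path) < len(best_path):
                best_path = path
    return PathReport(
        path_exists=best_path is not None,
        path_pockets=list(best_path) if best_path else [],
        labels=labels,
    )


def write_pocket_points_pdb(pocket_set: PocketSet, path) -> None:
    """Write pocket grid points as HETATM pseudo-atoms for visualization."""
    with open(path, "w") as fh:
        serial = 1
        for p in pocket_set.pockets:
            for x, y, z in p.points:
                fh.write(
                    f"HETATM{serial:>5d}  O   PKT A{p.id + 1:>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           O\n"
                )
                serial += 1
        fh.write("END\n")
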