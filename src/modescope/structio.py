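"""Structure and trajectory I/O plus named residue-region selections.

The unit of geometry is :class:`StructureModel` (a flat, array-backed atom
table); multi-model PDB files become :class:`Trajectory` objects (fixed
topology, per-frame coordinates). Residue regions relevant to the KIT
cytoplasmic region (juxtamembrane fragments, P-loop, C-helix, A-loop) are
provided as a default :class:`RegionMap` using the author-assigned KIT
numbering (residues 547-935), 1-based with closed intervals.

PDB reading and writing are delegated to biotite; alternate locations are
resolved by highest occupancy and insertion codes are rejected, so parsing
is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from . import _elements


class StructureError(ValueError):
    """Raised for malformed, empty or unrepresentable structures."""


class SelectionError(ValueError):
    """Raised when a region resolves to zero atoms."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """Array-backed atom table: one row per atom, coordinates in Å."""

    serials: np.ndarray        # (N,) int
    atom_names: np.ndarray     # (N,) str
    res_names: np.ndarray      # (N,) str
    res_ids: np.ndarray        # (N,) int, author numbering, 1-based
    chain_ids: np.ndarray      # (N,) str
    elements: np.ndarray       # (N,) str, upper-case
    coords: np.ndarray         # (N, 3) float, Å
    masses: np.ndarray         # (N,) float, Da
    vdw_radii: np.ndarray      # (N,) float, Å
    apolar: np.ndarray         # (N,) bool

    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise StructureError(
                f"coordinate shape {coords.shape} does not match topology "
                f"({self.coords.shape})"
            )
        return replace(self, coords=coords)

    def validate(self) -> None:
        if self.n_atoms == 0:
            raise StructureError("structure contains zero atoms")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        if len(np.unique(self.serials)) != self.n_atoms:
            raise StructureError("duplicate atom serial numbers")
        if np.any(self.vdw_radii <= 0) or np.any(self.masses <= 0):
            raise StructureError("non-positive vdw radius or mass")
        for chain in np.unique(self.chain_ids):
            rid = self.res_ids[self.chain_ids == chain]
            if np.any(np.diff(rid) < 0):
                raise StructureError(
                    f"residue numbers decrease within chain {chain!r}"
                )


@dataclass
class Trajectory:
    """Ordered coordinate frames (Å) over a fixed topology, times in ps."""

    topology: StructureModel
    frames: np.ndarray                      # (F, N, 3) float
    times: np.ndarray                       # (F,) float ps, strictly increasing
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise StructureError(
                "every frame must have exactly the topology's atom count"
            )
        if len(self.times) != len(self.frames):
            raise StructureError("one timestamp per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise StructureError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.frames[i])


Interval = tuple[int, int]


@dataclass
class RegionMap:
    """Named residue regions: label -> list of closed 1-based intervals."""

    regions: dict[str, list[Interval]]

    def __post_init__(self) -> None:
        for label, ivs in self.regions.items():
            if not ivs:
                raise ValueError(f"region {label!r} has no intervals")
            for lo, hi in ivs:
                if hi < lo:
                    raise ValueError(f"empty interval {lo}-{hi} in {label!r}")

    def __getitem__(self, label: str) -> list[Interval]:
        return self.regions[label]

    def __contains__(self, label: str) -> bool:
        return label in self.regions

    def labels(self) -> list[str]:
        return list(self.regions)

    @classmethod
    def from_config(cls, text: str) -> "RegionMap":
        """Parse ``label = start-end[, start-end ...]`` lines; '#' comments."""
        regions: dict[str, list[Interval]] = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'label = start-end'")
            label, spec = (part.strip() for part in line.split("=", 1))
            if label in regions:
                raise ValueError(f"line {lineno}: duplicate label {label!r}")
            intervals = []
            for chunk in spec.split(","):
                lo_s, _, hi_s = chunk.strip().partition("-")
                try:
                    lo = int(lo_s)
                    hi = int(hi_s) if hi_s else lo
                except ValueError as exc:
                    raise ValueError(f"line {lineno}: bad interval {chunk!r}") from exc
                intervals.append((lo, hi))
            regions[label] = intervals
        return cls(regions)


def default_region_map() -> RegionMap:
    """KIT cytoplasmic-region defaults (author numbering 547-935).

    JM-P/JM-B/JM-S/JM-Z are the juxtamembrane proximal, buried, switch and
    zipper fragments; JMR is their contiguous union.
    """
    return RegionMap({
        "JM-P": [(547, 552)],
        "JM-B": [(553, 559)],
        "JM-S": [(560, 570)],
        "JM-Z": [(571, 581)],
        "JMR": [(547, 581)],
        "P-loop": [(596, 601)],
        "C-helix": [(631, 647)],
        "A-loop": [(810, 835)],
    })


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def _resolve_intervals(region, region_map: RegionMap | None) -> list[Interval]:
    if isinstance(region, str):
        rmap = region_map if region_map is not None else default_region_map()
        if region not in rmap:
            raise SelectionError(
                f"unknown region label {region!r}; known: {rmap.labels()}"
            )
        return rmap[region]
    if isinstance(region, tuple) and len(region) == 2:
        return [region]
    return [tuple(iv) for iv in region]


def select(
    model: StructureModel,
    region,
    atom_filter: str = "all",
    region_map: RegionMap | None = None,
) -> np.ndarray:
    """Resolve a region (label or interval(s)) to atom indices in topology order.

    ``atom_filter``: ``all``, ``heavy`` (exclude hydrogens) or ``calpha``
    (one CA atom per residue that has one).
    """
    intervals = _resolve_intervals(region, region_map)
    mask = np.zeros(model.n_atoms, dtype=bool)
    for lo, hi in intervals:
        mask |= (model.res_ids >= lo) & (model.res_ids <= hi)
    if atom_filter == "heavy":
        mask &= model.elements != "H"
    elif atom_filter == "calpha":
        mask &= (model.atom_names == "CA") & (model.elements == "C")
    elif atom_filter != "all":
        raise ValueError(f"unknown atom_filter {atom_filter!r}")
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        raise SelectionError(f"region {region!r} selects zero atoms")
    return indices


# ---------------------------------------------------------------------------
# atom property assignment
# ---------------------------------------------------------------------------

def infer_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name (used when the column is absent)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise StructureError(f"cannot infer element from atom name {atom_name!r}")
    two = stripped[:2].upper()
    if two in ("FE", "ZN", "MG", "CL", "BR", "SE", "NA") and len(atom_name.strip()) > 3:
        return two
    return stripped[0].upper()


def _apolar_flags(elements: np.ndarray, atom_names: np.ndarray) -> np.ndarray:
    # apolar = C/S atoms, minus the backbone carbonyl carbon which is bonded
    # to O (name-based heuristic; side-chain polar carbons are kept apolar,
    # which matches LIGPLOT-style contact conventions closely enough).
    apolar = np.isin(elements, ("C", "S"))
    apolar &= atom_names != "C"
    return apolar


def _annotate(
    serials, atom_names, res_names, res_ids, chain_ids, elements, coords
) -> StructureModel:
    elements = np.array(
        [e if e else infer_element(n) for e, n in zip(elements, atom_names)],
        dtype="U4",
    )
    radii = np.array([_elements.vdw_radius(e) for e in elements])
    masses = np.array([_elements.mass(e) for e in elements])
    model = StructureModel(
        serials=np.asarray(serials, dtype=int),
        atom_names=np.asarray(atom_names, dtype="U6"),
        res_names=np.asarray(res_names, dtype="U5"),
        res_ids=np.asarray(res_ids, dtype=int),
        chain_ids=np.asarray(chain_ids, dtype="U4"),
        elements=elements,
        coords=np.asarray(coords, dtype=float),
        masses=masses,
        vdw_radii=radii,
        apolar=_apolar_flags(elements, np.asarray(atom_names, dtype="U6")),
    )
    model.validate()
    return model


def build_model(
    atom_names,
    res_ids,
    coords,
    elements=None,
    res_names=None,
    chain_ids=None,
    serials=None,
) -> StructureModel:
    """Convenience constructor used by the synthetic generators."""
    n = len(atom_names)
    if elements is None:
        elements = [infer_element(a) for a in atom_names]
    if res_names is None:
        res_names = ["GLY"] * n
    if chain_ids is None:
        chain_ids = ["A"] * n
    if serials is None:
        serials = np.arange(1, n + 1)
    return _annotate(serials, atom_names, res_names, res_ids, chain_ids,
                     elements, coords)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _locate_bad_line(path) -> int | None:
    """Best-effort scan for the first unparseable ATOM/HETATM record."""
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        float(line[30:38])
                        float(line[38:46])
                        float(line[46:54])
                    except (ValueError, IndexError):
                        return lineno
    except OSError:
        return None
    return None


def _from_atom_array(arr: struc.AtomArray) -> StructureModel:
    if arr.array_length() == 0:
        raise StructureError("file contains zero atoms")
    if "ins_code" in arr.get_annotation_categories():
        ins = np.asarray(arr.ins_code)
        if np.any(ins != ""):
            raise StructureError("insertion codes are not supported")
    serials = (
        np.asarray(arr.atom_id)
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, arr.array_length() + 1)
    )
    return _annotate(
        serials,
        np.asarray(arr.atom_name),
        np.asarray(arr.res_name),
        np.asarray(arr.res_id),
        np.asarray(arr.chain_id),
        np.char.upper(np.asarray(arr.element)),
        arr.coord,
    )


def read_structure(path, model_policy: str = "first"):
    """Read a PDB file.

    ``model_policy='first'`` returns a :class:`StructureModel` from the first
    MODEL; ``'all'`` returns a :class:`Trajectory` built from all MODEL
    blocks (identical topology required). Missing element columns are
    inferred from atom names; vdw radii and masses are assigned from the
    bundled element table.
    """
    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    try:
        pdb = PDBFile.read(str(path))
        if model_policy == "first":
            arr = pdb.get_structure(
                model=1, altloc="occupancy", extra_fields=["atom_id"]
            )
            return _from_atom_array(arr)
        stack = pdb.get_structure(altloc="occupancy", extra_fields=["atom_id"])
    except StructureError:
        raise
    except Exception as exc:
        lineno = _locate_bad_line(path)
        where = f" at line {lineno}" if lineno else ""
        raise StructureError(f"cannot parse PDB file {path}{where}: {exc}") from exc
    if stack.stack_depth() == 0 or stack.array_length() == 0:
        raise StructureError("file contains zero atoms")
    topology = _from_atom_array(stack[0])
    times = np.arange(stack.stack_depth(), dtype=float)
    return Trajectory(topology=topology, frames=stack.coord.copy(), times=times)


def _to_atom_array(model: StructureModel) -> struc.AtomArray:
    arr = struc.AtomArray(model.n_atoms)
    arr.coord = np.asarray(model.coords, dtype=np.float32)
    arr.chain_id = model.chain_ids
    arr.res_id = model.res_ids
    arr.res_name = model.res_names
    arr.atom_name = model.atom_names
    arr.element = model.elements
    arr.set_annotation("atom_id", model.serials.astype(int))
    arr.hetero = np.zeros(model.n_atoms, dtype=bool)
    return arr


def write_structure(model, path) -> None:
    """Write a StructureModel or Trajectory as (multi-model) PDB."""
    if isinstance(model, Trajectory):
        if model.n_frames == 0:
            raise StructureError("refusing to write an empty trajectory")
        topo = model.topology
    else:
        topo = model
        if topo.n_atoms == 0:
            raise StructureError("refusing to write an empty structure")
    bad = np.flatnonzero(topo.res_ids > 9999)
    if len(bad):
        raise StructureError(
            f"residue number {topo.res_ids[bad[0]]} (atom serial "
            f"{topo.serials[bad[0]]}) exceeds the PDB format limit of 9999"
        )
    pdb = PDBFile()
    if isinstance(model, Trajectory):
        base = _to_atom_array(topo)
        stack = struc.stack(
            [base] * model.n_frames
        )
        stack.coord = np.asarray(model.frames, dtype=np.float32)
        pdb.set_structure(stack)
    else:
        pdb.set_structure(_to_atom_array(model))
    pdb.write(str(path))


def write_series_tsv(path, times, values, value_name: str = "value") -> None:
    """Write a scalar per-frame series as TSV (columns: time_ps, <name>)."""
    import pandas as pd

    pd.DataFrame({"time_ps": times, value_name: values}).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )
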