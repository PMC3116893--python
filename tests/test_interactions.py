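import numpy as np
import pytest

from modescope import interactions as ia
from modescope.structio import Trajectory, build_model


def tiny_hbond_system(d_ha=2.0, angle_deg=180.0):
    """Donor N with H, acceptor O; H···A distance and DHA angle adjustable."""
    n = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    theta = np.deg2rad(180.0 - angle_deg)
    a = h + d_ha * np.array([np.cos(theta), np.sin(theta), 0.0])
    return build_model(["N", "H", "O"], [1, 1, 2], np.vstack([n, h, a]),
                       elements=["N", "H", "O"])


class TestHbondDetection:
    def test_collinear_geometry_inside_defaults_detected(self):
        model = tiny_hbond_system(d_ha=2.0, angle_deg=180.0)
        events = ia.detect_hbonds(model)
        assert len(events) == 1
        ev = events[0]
        assert ev.distance == pytest.approx(2.0)
        assert ev.angle == pytest.approx(180.0)

    def test_long_donor_acceptor_distance_rejected(self):
        model = tiny_hbond_system(d_ha=4.5)   # D-A = 5.5 Å
        assert ia.detect_hbonds(model) == []

    def test_bent_geometry_rejected(self):
        model = tiny_hbond_system(d_ha=2.0, angle_deg=100.0)
        assert ia.detect_hbonds(model) == []

    def test_helix_has_i_to_i_plus_4_bonds_only(self, helix):
        events = ia.detect_hbonds(helix)
        offsets = {e.res_i - e.res_j for e in events}
        assert offsets == {4}
        donors = {e.res_i for e in events}
        assert donors == set(range(5, 13))   # every interior N-H donates

    def test_rigid_body_invariance(self, helix):
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(random_state=5).as_matrix()
        moved = helix.with_coords(helix.coords @ rot.T + 11.0)
        ref = {(e.atom_i, e.atom_j) for e in ia.detect_hbonds(helix)}
        new = {(e.atom_i, e.atom_j) for e in ia.detect_hbonds(moved)}
        assert ref == new

    def test_hydrogen_free_structure_uses_fallback(self, caplog):
        model = build_model(["N", "O"], [1, 2],
                            [[0, 0, 0], [3.0, 0, 0]], elements=["N", "O"])
        with caplog.at_level("WARNING"):
            events = ia.detect_hbonds(model)
        assert len(events) == 1
        assert events[0].angle is None
        assert any("no hydrogens" in r.message for r in caplog.records)


class TestHydrophobicDetection:
    def test_apolar_pair_within_cutoff_detected(self):
        model = build_model(["CB", "CG"], [1, 2],
                            [[0, 0, 0], [4.0, 0, 0]], elements=["C", "C"])
        events = ia.detect_hydrophobic(model)
        assert len(events) == 1
        assert events[0].distance == pytest.approx(4.0)

    def test_pair_beyond_cutoff_rejected(self):
        model = build_model(["CB", "CG"], [1, 2],
                            [[0, 0, 0], [5.0, 0, 0]], elements=["C", "C"])
        assert ia.detect_hydrophobic(model) == []

    def test_same_residue_pairs_excluded(self):
        model = build_model(["CB", "CG"], [1, 1],
                            [[0, 0, 0], [2.0, 0, 0]], elements=["C", "C"])
        assert ia.detect_hydrophobic(model) == []

    def test_polar_atoms_never_count(self):
        model = build_model(["N", "O"], [1, 2],
                            [[0, 0, 0], [3.0, 0, 0]], elements=["N", "O"])
        assert ia.detect_hydrophobic(model) == []

    def test_count_matches_brute_force_all_pairs_scan(self):
        rng = np.random.default_rng(12)
        n = 50
        coords = rng.uniform(0, 15, size=(n, 3))
        model = build_model(["CB"] * n, np.arange(1, n + 1), coords,
                            elements=["C"] * n)
        events = ia.detect_hydrophobic(model)
        brute = sum(
            1
            for i in range(n)
            for j in range(i + 1, n)
            if np.linalg.norm(coords[i] - coords[j]) <= ia.HYDROPHOBIC_D_MAX
        )
        assert len(events) == brute


def scheduled_contact_trajectory(fractions, n_frames=20):
    """Two apolar atoms per pair; each pair is in contact in a programmed
    fraction of frames (moved apart otherwise)."""
    n_pairs = len(fractions)
    # region A atoms first (residues 1..n), then region B (101..) so the
    # residue numbering stays nondecreasing along the chain
    names = ["CB"] * 2 * n_pairs
    res_ids = [p + 1 for p in range(n_pairs)] + \
        [100 + p + 1 for p in range(n_pairs)]
    base = [[0.0, 6.0 * p, 0.0] for p in range(n_pairs)] + \
        [[4.0, 6.0 * p, 0.0] for p in range(n_pairs)]
    model = build_model(names, np.array(res_ids), np.array(base),
                        elements=["C"] * 2 * n_pairs)
    frames = np.repeat(model.coords[None], n_frames, axis=0)
    for p, frac in enumerate(fractions):
        n_on = int(round(frac * n_frames))
        for f in range(n_on, n_frames):
            frames[f, n_pairs + p, 0] = 30.0   # break the contact
    return model, Trajectory(model, frames, np.arange(1.0, n_frames + 1.0))


class TestOccupancy:
    def test_programmed_fractions_recovered_exactly(self):
        model, traj = scheduled_contact_trajectory([0.2, 0.5, 0.9])
        region_a = np.flatnonzero(model.res_ids < 100)
        region_b = np.flatnonzero(model.res_ids >= 100)
        occ = ia.occupancy_map(traj, region_a, region_b,
                               contact_type="hydrophobic", threshold=0.15)
        got = dict(zip(occ.table["res_a"], occ.table["occupancy"]))
        assert got == {1: pytest.approx(0.2), 2: pytest.approx(0.5),
                       3: pytest.approx(0.9)}

    def test_below_threshold_pair_absent(self):
        model, traj = scheduled_contact_trajectory([0.1, 0.5])
        region_a = np.flatnonzero(model.res_ids < 100)
        region_b = np.flatnonzero(model.res_ids >= 100)
        occ = ia.occupancy_map(traj, region_a, region_b,
                               contact_type="hydrophobic", threshold=0.15)
        assert 1 not in set(occ.table["res_a"])
        assert 1 in set(occ.raw["res_a"])      # kept in the raw map

    def test_always_present_contact_has_occupancy_one(self):
        model, traj = scheduled_contact_trajectory([1.0])
        region_a = np.flatnonzero(model.res_ids < 100)
        region_b = np.flatnonzero(model.res_ids >= 100)
        occ = ia.occupancy_map(traj, region_a, region_b,
                               contact_type="hydrophobic")
        assert occ.table["occupancy"].iloc[0] == pytest.approx(1.0)

    def test_frame_by_frame_equals_pooled_event_bookkeeping(self):
        model, traj = scheduled_contact_trajectory([0.3, 0.7], n_frames=10)
        region_a = np.flatnonzero(model.res_ids < 100)
        region_b = np.flatnonzero(model.res_ids >= 100)
        occ = ia.occupancy_map(traj, region_a, region_b,
                               contact_type="hydrophobic", threshold=0.0)
        res_a = set(model.res_ids[region_a])
        res_b = set(model.res_ids[region_b])
        pooled: dict[tuple, set] = {}
        for f in range(traj.n_frames):
            for ev in ia.detect_hydrophobic(model, traj.frames[f], frame=f):
                pair = ((ev.res_i, ev.res_j) if ev.res_i in res_a
                        else (ev.res_j, ev.res_i))
                if pair[0] in res_a and pair[1] in res_b:
                    pooled.setdefault(pair, set()).add(f)
        expect = {p: len(fs) / traj.n_frames for p, fs in pooled.items()}
        got = {(r.res_a, r.res_b): r.occupancy
               for r in occ.raw.itertuples()}
        assert got == pytest.approx(expect)

    def test_overlapping_regions_rejected(self, toy_chain):
        traj = Trajectory(toy_chain, toy_chain.coords[None], [0.0])
        with pytest.raises(ValueError, match="disjoint"):
            ia.occupancy_map(traj, np.arange(5), np.arange(3, 8))


class TestProductiveTime:
    def test_two_replicas_pool_to_96_ns(self):
        assert ia.pooled_productive_time([50.0, 50.0], 2.0) == 96.0

    def test_short_replica_rejected(self):
        with pytest.raises(ValueError):
            ia.pooled_productive_time([1.5], 2.0)

    def test_frame_trimming_drops_relaxation(self, toy_chain):
        frames = np.repeat(toy_chain.coords[None], 10, axis=0)
        traj = Trajectory(toy_chain, frames, np.arange(1.0, 11.0) * 1000.0)
        trimmed = ia.productive_frames(traj, relaxation_ps=2000.0)
        assert trimmed.n_frames == 8
        assert trimmed.times[0] == 3000.0


class TestSasa:
    def test_isolated_atom_matches_closed_form(self):
        model = build_model(["C1"], [1], [[0, 0, 0]], elements=["C"])
        areas, _ = ia.sasa(model, probe_radius=1.5)
        assert areas[0] == pytest.approx(4 * np.pi * (1.7 + 1.5) ** 2,
                                         rel=0.01)

    def test_distant_atoms_are_additive(self):
        model = build_model(["C1", "C2"], [1, 2],
                            [[0, 0, 0], [100.0, 0, 0]], elements=["C", "C"])
        areas, _ = ia.sasa(model)
        assert areas[0] == pytest.approx(areas[1], rel=1e-9)
        assert areas.sum() == pytest.approx(2 * areas[0], rel=1e-9)

    def test_buried_atom_in_sealed_cavity(self):
        # tight shell: every probe position around the center is occluded
        from modescope import synthetic_data as sd
        shell = sd.make_cavity_structure(3.0, 25.0, 300, seed=3)
        coords = np.vstack([[0.0, 0.0, 0.0], shell.coords])
        names = ["C0"] + list(shell.atom_names)
        combined = build_model(names, np.arange(1, len(names) + 1), coords,
                               elements=["C"] * len(names))
        areas, _ = ia.sasa(combined)
        isolated = 4 * np.pi * (1.7 + 1.5) ** 2
        assert areas[0] < 0.01 * isolated

    def test_adding_atoms_never_increases_area(self, helix):
        areas_alone, _ = ia.sasa(helix)
        extra = build_model(
            list(helix.atom_names) + ["CX"],
            np.append(helix.res_ids, 99),
            np.vstack([helix.coords, helix.coords.mean(axis=0)]),
            elements=list(helix.elements) + ["C"],
        )
        areas_with, _ = ia.sasa(extra)
        assert np.all(areas_with[:helix.n_atoms] <= areas_alone + 1e-9)

    def test_negative_probe_rejected(self, helix):
        with pytest.raises(ValueError):
            ia.sasa(helix, probe_radius=-0.1)

    def test_per_residue_sums_atoms(self, helix):
        areas, per_res = ia.sasa(helix)
        total_from_atoms = areas.sum()
        assert per_res["area"].sum() == pytest.approx(total_from_atoms)

    def test_agrees_with_independent_implementation(self, helix):
        """Cross-check against biotite's Shrake-Rupley on the same radii."""
        import biotite.structure as struc
        arr = struc.AtomArray(helix.n_atoms)
        arr.coord = helix.coords.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id = helix.res_ids
        arr.res_name[:] = "ALA"
        arr.atom_name = helix.atom_names
        arr.element = helix.elements
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=960,
                            vdw_radii="Single")
        mine, _ = ia.sasa(helix, probe_radius=1.4)
        heavy = helix.elements != "H"
        assert mine[heavy].sum() == pytest.approx(np.nansum(theirs), rel=0.03)
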