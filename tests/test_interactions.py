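"""H-bond detection, contact counting, binding time and SASA partitioning."""

import numpy as np
import pandas as pd
import pytest

from memraft import interactions as ia
from memraft import synthetic as sy
from memraft.errors import AnalysisError, TopologyError
from memraft.trajectory import Frame, Topology, Trajectory

from conftest import make_point_topology, single_frame_traj


def _hbond_topology():
    """Donor(O)-H in residue 1, acceptor(O) in residue 2."""
    return Topology(
        pd.DataFrame(
            {
                "atom_id": [1, 2, 3],
                "atom_name": ["OD", "HD", "OA"],
                "residue_id": [1, 1, 2],
                "species": ["A", "A", "B"],
                "subregion": ["other"] * 3,
                "element": ["O", "H", "O"],
                "mass_amu": [16.0, 1.0, 16.0],
                "vdw_radius_nm": [0.18, 0.12, 0.18],
                "is_donor": [True, False, False],
                "is_hydrogen": [False, True, False],
                "is_acceptor": [False, False, True],
                "donor_of": [-1, 1, -1],
                "leaflet_hint": [""] * 3,
            }
        )
    )


def _triplet_frame(d_nm, angle_deg, box=6.0):
    """Donor at origin-ish, H along +x, acceptor at given D-A distance/angle."""
    r1 = 0.10
    theta = np.deg2rad(angle_deg)
    s = r1 * np.cos(theta) + np.sqrt(d_nm**2 - (r1 * np.sin(theta)) ** 2)
    d = np.array([3.0, 3.0, 3.0])
    h = d + [r1, 0.0, 0.0]
    a = h + s * np.array([-np.cos(theta), np.sin(theta), 0.0]) * -1.0
    # H->A direction at angle theta from H->D (= -x)
    a = h + s * (np.cos(theta) * np.array([-1.0, 0, 0]) + np.sin(theta) * np.array([0, 1.0, 0]))
    return Frame(np.stack([d, h, a]), np.full(3, box))


class TestHbonds:
    @pytest.mark.parametrize(
        "d,angle,expected",
        [
            (0.28, 180.0, 1),
            (0.28, 170.0, 1),
            (0.28, 120.0, 0),  # angle fail
            (0.305, 170.0, 0),  # distance fail
            (0.28, 149.0, 0),  # just under the angle cutoff
        ],
    )
    def test_geometric_criteria(self, d, angle, expected):
        rec = ia.detect_hbonds(_triplet_frame(d, angle), _hbond_topology())
        assert len(rec) == expected
        if expected:
            assert rec.iloc[0]["distance_nm"] == pytest.approx(d, abs=1e-9)
            assert rec.iloc[0]["angle_deg"] == pytest.approx(angle, abs=1e-6)

    def test_hydrogen_without_donor_parent_rejected(self):
        tab = _hbond_topology().table.copy()
        tab.loc[0, "is_donor"] = False
        top = Topology(tab)
        with pytest.raises(TopologyError, match="non-donor"):
            ia.detect_hbonds(_triplet_frame(0.28, 170.0), top)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_geometry_precision_recall_one(self, seed):
        frame, top, truth = sy.plant_hbond_geometries(60, 30, 30, seed=seed)
        rec = ia.detect_hbonds(frame, top)
        detected = set(zip(rec["donor_id"], rec["acceptor_id"]))
        planted = set(
            zip(truth.loc[truth.is_true, "donor_id"], truth.loc[truth.is_true, "acceptor_id"])
        )
        assert detected == planted  # precision = recall = 1.0

    def test_pair_filter_restricts_species(self):
        frame, top, truth = sy.plant_hbond_geometries(20, 0, 0, seed=5)
        rec = ia.detect_hbonds(frame, top, pair_filter=lambda d, a: d == "nonexistent")
        assert rec.empty

    def test_minimum_image_across_boundary(self):
        # donor/acceptor on opposite faces of a small box still bond
        frame = _triplet_frame(0.28, 175.0, box=6.0)
        coords = frame.coordinates + np.array([2.95, 0, 0])  # push across +x face
        rec = ia.detect_hbonds(Frame(coords, frame.box), _hbond_topology())
        assert len(rec) == 1
        assert rec.iloc[0]["distance_nm"] == pytest.approx(0.28, abs=1e-9)

    def test_per_hydroxyl_accounting(self):
        frame, top, truth = sy.plant_hbond_geometries(15, 0, 0, seed=6)
        rec = ia.detect_hbonds(frame, top)
        rec.insert(0, "frame", 0)
        per_oh = ia.hbonds_per_hydroxyl(rec, n_frames=1, ligand_species="PLANT")
        assert per_oh["mean_count"].sum() == pytest.approx(2 * 15)  # donor+acceptor ends


class TestContacts:
    def test_pair_within_cutoff(self):
        top = make_point_topology(2)
        traj = single_frame_traj([[1.0, 1.0, 1.0], [1.40, 1.0, 1.0]], [6.0, 6.0, 6.0])
        s = ia.count_contacts(traj, top, np.array([0]), np.array([1]), 0.45)
        assert s.counts[0] == 1

    def test_exactly_at_cutoff_excluded(self):
        top = make_point_topology(2)
        traj = single_frame_traj([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0]], [6.0, 6.0, 6.0])
        s = ia.count_contacts(traj, top, np.array([0]), np.array([1]), 0.5)
        assert s.counts[0] == 0

    @pytest.mark.parametrize("cutoff", [0.16, 0.45, 0.5])
    def test_grid_equals_brute_force(self, cutoff, rng):
        n = 400
        coords = rng.uniform(0, 3.5, (5, n, 3))
        traj = Trajectory(coords, np.full((5, 3), 3.5))
        top = make_point_topology(n)
        a, b = np.arange(150), np.arange(150, n)
        g = ia.count_contacts(traj, top, a, b, cutoff, method="grid")
        br = ia.count_contacts(traj, top, a, b, cutoff, method="brute")
        assert np.array_equal(g.counts, br.counts)

    def test_translation_by_box_vector_invariant(self, rng):
        n = 100
        box = np.array([4.0, 4.0, 4.0])
        coords = rng.uniform(0, 4, (1, n, 3))
        top = make_point_topology(n)
        a, b = np.arange(40), np.arange(40, n)
        base = ia.count_contacts(Trajectory(coords, box[None]), top, a, b, 0.5)
        shifted = ia.count_contacts(
            Trajectory(coords + box * np.array([2.0, -1.0, 3.0]), box[None]), top, a, b, 0.5
        )
        assert np.array_equal(base.counts, shifted.counts)

    def test_by_subregion_split_sums_to_total(self, ld_config, rng):
        frame, top = ld_config
        lig = rng.uniform(0, frame.box, (10, 3))
        coords = np.vstack([frame.coordinates, lig])
        tab = pd.concat(
            [top.table, make_point_topology(10).table.assign(
                atom_id=np.arange(top.n_atoms + 1, top.n_atoms + 11),
                residue_id=top.table["residue_id"].max() + 1,
            )],
            ignore_index=True,
        )
        top2 = Topology(tab)
        traj = single_frame_traj(coords, frame.box)
        lig_idx = np.arange(top.n_atoms, top.n_atoms + 10)
        lip_idx = np.arange(top.n_atoms)
        split = ia.count_contacts(traj, top2, lig_idx, lip_idx, 0.6, by_subregion=True)
        total = ia.count_contacts(traj, top2, lig_idx, lip_idx, 0.6)
        assert sum(s.counts[0] for s in split.values()) == total.counts[0]

    def test_hydrogens_excluded_by_default(self, lo_config):
        frame, top = lo_config
        psm = top.atoms_of_species("PSM")
        chol = top.atoms_of_species("CHOL")
        s = ia.count_contacts(single_frame_traj(frame.coordinates, frame.box), top, psm, chol, 0.7)
        s_h = ia.count_contacts(
            single_frame_traj(frame.coordinates, frame.box), top, psm, chol, 0.7, heavy_only=False
        )
        assert s_h.counts[0] >= s.counts[0]

    def test_cutoff_beyond_half_box_rejected(self):
        top = make_point_topology(2)
        traj = single_frame_traj([[0.1, 0.1, 0.1], [0.5, 0.5, 0.5]], [1.0, 1.0, 1.0])
        with pytest.raises(AnalysisError, match="half"):
            ia.count_contacts(traj, top, np.array([0]), np.array([1]), 0.6)

    def test_empty_group_rejected(self):
        top = make_point_topology(2)
        traj = single_frame_traj([[1, 1, 1], [2, 2, 2]], [5, 5, 5])
        with pytest.raises(AnalysisError, match="non-empty"):
            ia.count_contacts(traj, top, np.array([], dtype=int), np.array([1]), 0.4)


class TestMinDistance:
    def test_known_separation(self):
        traj = single_frame_traj([[1.0, 1.0, 1.0], [2.0, 1.0, 1.0]], [6.0, 6.0, 6.0])
        d = ia.min_distance(traj, np.array([0]), np.array([1]))
        assert d[0] == pytest.approx(1.0)

    def test_coincident_atoms_zero(self):
        traj = single_frame_traj([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]], [6.0, 6.0, 6.0])
        assert ia.min_distance(traj, np.array([0]), np.array([1]))[0] == 0.0

    def test_grid_equals_brute(self, rng):
        coords = rng.uniform(0, 4, (4, 80, 3))
        traj = Trajectory(coords, np.full((4, 3), 4.0))
        a, b = np.arange(30), np.arange(30, 80)
        assert np.allclose(
            ia.min_distance(traj, a, b, method="grid"),
            ia.min_distance(traj, a, b, method="brute"),
        )


class TestBindingTime:
    def test_worked_example(self):
        s = ia.ContactSeries(np.array([900, 850, 700, 820]), dt=0.1, cutoff_nm=0.16)
        res = ia.strong_binding_time(s, 800)
        assert res.strong_binding_time_ns == pytest.approx(0.3)

    def test_all_below_threshold_zero(self):
        s = ia.ContactSeries(np.array([100, 200, 800]), dt=0.1, cutoff_nm=0.16)
        assert ia.strong_binding_time(s, 800).strong_binding_time_ns == 0.0

    def test_threshold_minus_one_gives_full_length(self):
        s = ia.ContactSeries(np.zeros(50, dtype=int), dt=0.2, cutoff_nm=0.16)
        assert ia.strong_binding_time(s, -1).strong_binding_time_ns == pytest.approx(10.0)

    def test_monotone_nonincreasing_in_threshold(self, rng):
        s = ia.ContactSeries(rng.integers(0, 2000, 500), dt=0.1, cutoff_nm=0.16)
        times = [
            ia.strong_binding_time(s, th).strong_binding_time_ns
            for th in [-1, 0, 200, 800, 1500, 3000]
        ]
        assert all(a >= b for a, b in zip(times, times[1:]))

    def test_zero_dispersion_recovery_exact(self):
        spec = sy.BindingKineticsSpec(dispersion=0.0, n_frames=20000, dt=0.1, seed=17)
        series, _, true_t = sy.simulate_binding_trace(spec)
        res = ia.strong_binding_time(series, 800)
        assert res.strong_binding_time_ns == pytest.approx(true_t)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        top = make_point_topology(1, radius=0.20)
        frame = Frame(np.array([[3.0, 3.0, 3.0]]), np.full(3, 8.0))
        part = ia.sasa_partition(frame, top, np.array([0]), probe_radius_nm=0.14)
        expected = 4 * np.pi * 3.4**2  # (2.0 + 1.4)^2 in Angstrom
        assert part.total_A2 == pytest.approx(expected, rel=1e-6)
        assert part.solvent_A2 == pytest.approx(part.total_A2)
        assert part.headgroup_A2 == 0.0 and part.tail_A2 == 0.0

    def test_occlusion_monotone(self):
        top = make_point_topology(2, radius=0.20)
        iso = 4 * np.pi * 3.4**2
        frame = Frame(np.array([[3.0, 3, 3], [3.5, 3, 3]]), np.full(3, 8.0))
        part = ia.sasa_partition(frame, top, np.array([0]))
        assert part.total_A2 < iso

    def test_partition_sums_to_total(self, rng):
        n = 30
        coords = 3.0 + rng.normal(0, 0.25, (n, 3))
        tab = make_point_topology(n).table
        tab.loc[10:19, "subregion"] = "phosphate"
        tab.loc[20:, "subregion"] = "tails"
        top = Topology(tab)
        frame = Frame(coords, np.full(3, 10.0))
        part = ia.sasa_partition(frame, top, np.arange(10))
        assert part.headgroup_A2 + part.tail_A2 + part.solvent_A2 == pytest.approx(
            part.total_A2, rel=1e-9
        )
        assert part.headgroup_A2 > 0 and part.tail_A2 > 0

    def test_self_convergence(self, rng):
        n = 20
        coords = 3.0 + rng.normal(0, 0.2, (n, 3))
        top = make_point_topology(n, radius=0.17)
        frame = Frame(coords, np.full(3, 10.0))
        lo = ia.sasa_partition(frame, top, np.arange(n), n_points=960)
        hi = ia.sasa_partition(frame, top, np.arange(n), n_points=10000)
        assert lo.total_A2 == pytest.approx(hi.total_A2, rel=0.02)

    def test_against_independent_implementation(self, rng):
        """Cross-check total SASA against biotite's Shrake-Rupley."""
        import biotite.structure as struc

        n = 25
        coords_nm = 3.0 + rng.normal(0, 0.22, (n, 3))
        radius = 0.17
        top = make_point_topology(n, radius=radius)
        frame = Frame(coords_nm, np.full(3, 12.0))
        ours = ia.sasa_partition(frame, top, np.arange(n), n_points=960)

        atoms = struc.AtomArray(n)
        atoms.coord = coords_nm * 10.0  # nm -> Angstrom
        atoms.element = np.array(["C"] * n)
        atoms.res_id = np.arange(1, n + 1)
        atoms.res_name = np.array(["LIG"] * n)
        atoms.atom_name = np.array(["C"] * n)
        ref = struc.sasa(
            atoms,
            probe_radius=1.4,
            point_number=960,
            vdw_radii=np.full(n, radius * 10.0),
        ).sum()
        assert ours.total_A2 == pytest.approx(ref, rel=0.02)

    def test_missing_radius_rejected(self):
        tab = make_point_topology(2).table.copy()
        tab.loc[1, "vdw_radius_nm"] = np.nan
        with pytest.raises(Exception):
            top = Topology(tab)
            ia.sasa_partition(
                Frame(np.zeros((2, 3)) + 1.0, np.full(3, 5.0)), top, np.array([0])
            )
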