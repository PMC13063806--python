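"""Structural metrics: leaflets, APL, thickness, K_A, density regions."""

import numpy as np
import pytest

from memraft import structure as st
from memraft import synthetic as sy
from memraft.errors import AnalysisError
from memraft.synthetic import KB
from memraft.trajectory import Trajectory

from conftest import make_point_topology, single_frame_traj


class TestLeaflets:
    def test_exact_two_way_split(self, ld_config):
        frame, top = ld_config
        leaflets = st.assign_leaflets(frame, top)
        counts = leaflets["leaflet"].value_counts()
        assert counts["upper"] == 40 and counts["lower"] == 40

    def test_lo_membrane_120_per_leaflet(self, lo_config):
        frame, top = lo_config
        leaflets = st.assign_leaflets(frame, top)
        counts = leaflets["leaflet"].value_counts()
        assert counts["upper"] == 120 and counts["lower"] == 120

    def test_midplane_tie_goes_upper_with_warning(self, ld_config):
        frame, top = ld_config
        coords = frame.coordinates.copy()
        refs = top.reference_atoms()
        # force every reference atom onto one plane: midplane == plane
        coords[refs["atom_index"], 2] = 4.5
        from memraft.trajectory import Frame

        with pytest.warns(UserWarning, match="midplane"):
            leaflets = st.assign_leaflets(Frame(coords, frame.box), top)
        assert (leaflets["leaflet"] == "upper").all()


class TestAplThickness:
    def test_static_box_apl_exact(self, ld_short_traj):
        traj, top = ld_short_traj
        apl, _, _ = st.area_per_lipid(traj, top)
        assert apl == pytest.approx(0.651)

    def test_apl_linear_in_box_rescale(self, ld_short_traj):
        traj, top = ld_short_traj
        scaled = Trajectory(
            traj.coordinates, traj.boxes * np.array([2.0, 1.0, 1.0]), traj.times
        )
        apl, _, _ = st.area_per_lipid(traj, top)
        apl2, _, _ = st.area_per_lipid(scaled, top)
        assert apl2 == pytest.approx(2 * apl)

    def test_thickness_matches_target(self, ld_short_traj):
        traj, top = ld_short_traj
        th, _, _ = st.bilayer_thickness(traj, top)
        assert th == pytest.approx(3.90, abs=0.02)

    def test_rigid_translation_invariance(self, ld_short_traj):
        traj, top = ld_short_traj
        shifted = Trajectory(
            traj.coordinates + np.array([0.0, 0.0, 1.3]), traj.boxes, traj.times
        )
        th, _, _ = st.bilayer_thickness(traj, top)
        th2, _, _ = st.bilayer_thickness(shifted, top)
        apl, _, _ = st.area_per_lipid(traj, top)
        apl2, _, _ = st.area_per_lipid(shifted, top)
        assert th2 == pytest.approx(th) and apl2 == pytest.approx(apl)

    def test_frame_order_irrelevant(self, ld_short_traj):
        traj, top = ld_short_traj
        perm = np.random.default_rng(0).permutation(traj.n_frames)
        shuffled = Trajectory(traj.coordinates[perm], traj.boxes[perm], traj.times)
        assert st.area_per_lipid(shuffled, top)[0] == pytest.approx(
            st.area_per_lipid(traj, top)[0]
        )


class TestCompressibility:
    def test_direct_arithmetic(self, rng):
        a = rng.normal(26.0, 0.32, 5000)
        k_a, meta = st.area_compressibility(a, 310.0)
        expected = KB * 310.0 * a.mean() * 1e-18 / (a.var(ddof=1) * 1e-36)
        assert k_a == pytest.approx(expected)

    def test_halved_variance_doubles_ka(self, rng):
        base = rng.normal(0.0, 1.0, 2000)
        a1 = 26.0 + base * 0.3
        a2 = 26.0 + base * 0.3 / np.sqrt(2)
        k1, _ = st.area_compressibility(a1, 310.0)
        k2, _ = st.area_compressibility(a2, 310.0)
        assert k2 / k1 == pytest.approx(2.0, rel=1e-3)

    def test_recovery_from_generator(self, ld_config):
        frame, top = ld_config
        errs = []
        for seed in range(5):
            spec = sy.DynamicsSpec(
                {"POPC": 1.2e-7},
                n_frames=10000,
                dt=0.1,
                k_a_target=1.08839,
                temperature=310.0,
                seed=100 + seed,
            )
            traj, _ = sy.simulate_lateral_diffusion(frame, top, spec, keep="reference")
            k_a, _ = st.area_compressibility(traj.areas, 310.0)
            errs.append(abs(k_a - 1.08839) / 1.08839)
        assert np.median(errs) <= 0.10

    def test_degenerate_series_rejected(self):
        with pytest.raises(AnalysisError, match="degenerate"):
            st.area_compressibility(np.full(200, 26.0), 310.0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(AnalysisError, match="100"):
            st.area_compressibility(np.linspace(25, 27, 50), 310.0)


class TestDensityProfile:
    def test_single_atom_at_midplane(self):
        # a lone "lipid" defines the midplane; its mass lands in one bin
        top = make_point_topology(1, species="POPC", subregion="phosphate", mass=100.0)
        top.table.loc[0, "atom_name"] = "P"
        traj = single_frame_traj([[2.0, 2.0, 3.0]], [4.0, 4.0, 6.0])
        prof = st.mass_density_profile(traj, top, np.array([0]), 0.1)
        nz = prof.density_kg_m3 > 0
        assert nz.sum() == 1
        vol = 4.0 * 4.0 * prof.bin_width_nm
        assert prof.density_kg_m3[nz][0] == pytest.approx(100.0 / vol * 1.66053906660)

    def test_mass_conservation(self, ld_short_traj):
        traj, top = ld_short_traj
        prof = st.mass_density_profile(traj, top, np.arange(top.n_atoms), 0.1)
        vol = traj.boxes[0, 0] * traj.boxes[0, 1] * prof.bin_width_nm
        integral = prof.density_kg_m3.sum() * vol / 1.66053906660
        assert integral == pytest.approx(top.table["mass_amu"].sum(), rel=1e-3)

    def test_symmetric_bilayer_gives_symmetric_profile(self, ld_short_traj):
        traj, top = ld_short_traj
        prof = st.mass_density_profile(traj, top, np.arange(top.n_atoms), 0.15)
        d = prof.density_kg_m3
        asym = np.abs(d - d[::-1]).sum() / d.sum()
        assert asym < 0.15  # statistical symmetry within jitter noise

    def test_empty_selection_rejected(self, ld_short_traj):
        traj, top = ld_short_traj
        with pytest.raises(AnalysisError, match="empty"):
            st.mass_density_profile(traj, top, np.array([], dtype=int), 0.1)


class TestRegions:
    @pytest.fixture
    def scheme(self, ld_short_traj):
        traj, top = ld_short_traj
        head = st.mass_density_profile(
            traj, top, top.atoms_of_subregion("choline", "phosphate", "glycerol"), 0.1
        )
        tails = st.mass_density_profile(traj, top, top.atoms_of_subregion("tails"), 0.1)
        return st.classify_regions(head, tails), head.z_centers_nm

    def test_boundaries_strictly_ordered(self, scheme):
        s, _ = scheme
        b = s.boundaries
        assert b[0] < b[1] < b[2] < b[3]

    def test_midplane_is_region_5_bulk_is_region_1(self, scheme):
        s, _ = scheme
        assert s.region_of(0.0) == 5
        assert s.region_of(4.4) == 1
        assert s.region_of(-4.4) == 1  # symmetric in |z|

    def test_ligand_at_midplane_100pct_region5(self, scheme):
        s, z = scheme
        dens = np.where(np.abs(z) < 0.05, 50.0, 0.0)
        occ, peak = st.locate_ligand(st.DensityProfile(z, dens, 0.1), s)
        assert peak == 5 and occ[5] == pytest.approx(1.0)

    def test_ligand_in_bulk_100pct_region1(self, scheme):
        s, z = scheme
        dens = np.where(np.abs(np.abs(z) - 4.3) < 0.06, 50.0, 0.0)
        occ, peak = st.locate_ligand(st.DensityProfile(z, dens, 0.1), s)
        assert peak == 1 and occ[1] == pytest.approx(1.0)

    def test_ligand_at_glycerol_plane_peaks_region3(self, ld_short_traj, scheme):
        s, z = scheme
        traj, top = ld_short_traj
        gly = top.atoms_of_subregion("glycerol")
        mid = traj.coordinates[0, top.reference_atoms()["atom_index"], 2].mean()
        gly_z = np.abs(traj.coordinates[0, gly, 2] - mid).mean()
        prof = st.DensityProfile(z, np.where(np.abs(np.abs(z) - gly_z) < 0.08, 10.0, 0.0), 0.1)
        occ, peak = st.locate_ligand(prof, s)
        assert peak == 3

    def test_empty_ligand_profile_rejected(self, scheme):
        s, z = scheme
        with pytest.raises(AnalysisError, match="no mass"):
            st.locate_ligand(st.DensityProfile(z, np.zeros_like(z), 0.1), s)

    def test_manual_boundaries_validated(self):
        with pytest.raises(AnalysisError, match="increasing"):
            st.RegionScheme((1.0, 0.5, 2.0, 3.0))
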