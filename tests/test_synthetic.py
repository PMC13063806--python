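"""Ground-truth and determinism contracts of the synthetic generators."""

import numpy as np
import pytest
from scipy import stats as sps

from memraft import synthetic as sy
from memraft.errors import SpecError


class TestBilayerConfig:
    def test_ld_composition_and_area(self, ld_config):
        frame, top = ld_config
        assert frame.area == pytest.approx(40 * 0.651)
        assert top.table["residue_id"].nunique() == 80
        assert (top.table["species"] == "POPC").all()

    def test_lo_composition_ratio(self, lo_config):
        _, top = lo_config
        per_species = top.table.groupby("species")["residue_id"].nunique()
        assert per_species["CHOL"] == 160 and per_species["PSM"] == 80
        assert per_species["CHOL"] / per_species["PSM"] == 2
        # identical composition in both leaflets
        per_leaflet = top.table.groupby(["leaflet_hint", "species"])[
            "residue_id"
        ].nunique()
        assert per_leaflet["upper"].equals(per_leaflet["lower"])

    def test_single_lipid_identity(self):
        frame, _ = sy.build_bilayer_config(
            sy.BilayerSpec({"POPC": 1}, apl_target=1.0, thickness_target=3.0, box_z=8.0)
        )
        assert frame.area == pytest.approx(1.0)

    def test_reference_planes_separated_by_thickness(self, ld_config):
        frame, top = ld_config
        refs = top.reference_atoms()
        z = frame.coordinates[refs["atom_index"], 2]
        upper = z[z > frame.box[2] / 2]
        lower = z[z < frame.box[2] / 2]
        assert upper.mean() - lower.mean() == pytest.approx(3.90)

    def test_hbond_roles_follow_chemistry(self, lo_config, ld_config):
        _, lo_top = lo_config
        _, ld_top = ld_config
        popc = ld_top.table[ld_top.table["species"] == "POPC"]
        assert not popc["is_donor"].any()  # POPC oxygens accept only
        assert popc["is_acceptor"].any()
        psm = lo_top.table[lo_top.table["species"] == "PSM"]
        chol = lo_top.table[lo_top.table["species"] == "CHOL"]
        assert psm["is_donor"].any()
        o3 = chol[chol["atom_name"] == "O3"]
        assert o3["is_donor"].all() and o3["is_acceptor"].all()

    @pytest.mark.parametrize(
        "kw",
        [
            {"composition_per_leaflet": {}},
            {"composition_per_leaflet": {"POPC": 0}},
            {"composition_per_leaflet": {"POPC": 4}, "apl_target": -1.0},
            {"composition_per_leaflet": {"POPC": 4}, "thickness_target": 10.0, "box_z": 9.0},
        ],
    )
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(SpecError):
            sy.BilayerSpec(**kw)

    def test_same_seed_byte_identical(self):
        a, ta = sy.build_bilayer_config(sy.ld_spec(seed=7))
        b, tb = sy.build_bilayer_config(sy.ld_spec(seed=7))
        assert np.array_equal(a.coordinates, b.coordinates)
        assert ta.table.equals(tb.table)


class TestLateralDiffusion:
    def test_zero_d_freezes_everything(self, ld_config):
        frame, top = ld_config
        spec = sy.DynamicsSpec({"POPC": 0.0}, n_frames=20, dt=0.1, z_jitter_sd=0.0, seed=3)
        traj, _ = sy.simulate_lateral_diffusion(frame, top, spec)
        assert np.allclose(traj.coordinates, traj.coordinates[0])

    def test_step_variance_matches_unit_conversion(self, ld_config):
        # D = 1.2e-7 cm^2/s = 0.012 nm^2/ns; per-axis sd over dt=1 ns = sqrt(0.024)
        frame, top = ld_config
        spec = sy.DynamicsSpec(
            {"POPC": 1.2e-7}, n_frames=2000, dt=1.0, z_jitter_sd=0.0, seed=4
        )
        traj, rtop = sy.simulate_lateral_diffusion(frame, top, spec, keep="reference")
        from memraft.trajectory import minimum_image

        steps = minimum_image(np.diff(traj.coordinates[:, :, :2], axis=0), traj.boxes[0, :2])
        sd = steps.std()
        expected = np.sqrt(0.024)
        n = steps.size
        assert sd == pytest.approx(expected, rel=4.0 / np.sqrt(2 * n))

    def test_species_msd_slopes_scale_with_d(self, lo_config):
        frame, top = lo_config
        spec = sy.DynamicsSpec(
            {"PSM": 1.2e-7, "CHOL": 1.2e-8},
            n_frames=4000,
            dt=0.1,
            z_jitter_sd=0.0,
            seed=5,
        )
        traj, rtop = sy.simulate_lateral_diffusion(frame, top, spec, keep="reference")
        from memraft import dynamics as dy

        tracks = dy.unwrap_lateral(traj, rtop, remove_com_drift=False)
        table = dy.species_diffusion(tracks, (2.0, 40.0)).set_index("species")
        ratio = table.loc["PSM", "d_cm2_s"] / table.loc["CHOL", "d_cm2_s"]
        assert ratio == pytest.approx(10.0, rel=0.25)

    def test_area_series_mean_var_within_3se(self, ld_config):
        frame, top = ld_config
        mean, var = frame.area, 0.05
        spec = sy.DynamicsSpec(
            {"POPC": 1.2e-7},
            n_frames=5000,
            dt=0.1,
            area_fluctuation=(mean, var),
            seed=6,
        )
        traj, _ = sy.simulate_lateral_diffusion(frame, top, spec, keep="reference")
        a = traj.areas
        se_mean = np.sqrt(var / a.size)
        assert abs(a.mean() - mean) < 3 * se_mean
        se_var = var * np.sqrt(2.0 / (a.size - 1))
        assert abs(a.var(ddof=1) - var) < 3 * se_var

    def test_determinism(self, ld_config):
        frame, top = ld_config
        spec = sy.DynamicsSpec({"POPC": 1.2e-7}, n_frames=50, dt=0.1, seed=9)
        t1, _ = sy.simulate_lateral_diffusion(frame, top, spec)
        t2, _ = sy.simulate_lateral_diffusion(frame, top, spec)
        assert np.array_equal(t1.coordinates, t2.coordinates)

    def test_negative_d_rejected(self):
        with pytest.raises(SpecError):
            sy.DynamicsSpec({"POPC": -1e-7})


class TestBindingTrace:
    def test_never_unbinds(self):
        spec = sy.BindingKineticsSpec(
            k_on=0.0, k_off=0.0, start_state="bound", n_frames=100, dt=0.5, seed=1
        )
        _, states, true_t = sy.simulate_binding_trace(spec)
        assert states.all()
        assert true_t == pytest.approx(100 * 0.5)

    def test_stationary_occupancy(self):
        spec = sy.BindingKineticsSpec(
            k_on=0.01, k_off=0.01, n_frames=50000, dt=0.1, dispersion=0.0, seed=2
        )
        _, states, _ = sy.simulate_binding_trace(spec)
        occ = states.mean()
        # stationary occupancy k_on/(k_on+k_off) = 0.5; correlated series, so
        # use the effective sample size n * dt * (k_on + k_off) / 2
        n_eff = 50000 * 0.1 * 0.02 / 2
        assert abs(occ - 0.5) < 3 * 0.5 / np.sqrt(n_eff)

    def test_zero_dispersion_thresholding_recovers_states(self):
        spec = sy.BindingKineticsSpec(
            contact_level_bound=1000,
            contact_level_unbound=10,
            dispersion=0.0,
            n_frames=5000,
            dt=0.1,
            seed=3,
        )
        series, states, _ = sy.simulate_binding_trace(spec)
        assert np.array_equal(series.counts > 800, states.astype(bool))

    def test_level_ordering_enforced(self):
        with pytest.raises(SpecError):
            sy.BindingKineticsSpec(contact_level_bound=5, contact_level_unbound=10)


class TestPlantedHbonds:
    def test_truth_labels_match_planted_geometry(self):
        _, _, truth = sy.plant_hbond_geometries(30, 15, 15, seed=4)
        inside = (truth["distance_nm"] <= 0.30) & (truth["angle_deg"] >= 150.0)
        assert (inside == truth["is_true"]).all()
        assert truth["is_true"].sum() == 30

    def test_determinism(self):
        f1, _, t1 = sy.plant_hbond_geometries(10, 5, 5, seed=8)
        f2, _, t2 = sy.plant_hbond_geometries(10, 5, 5, seed=8)
        assert np.array_equal(f1.coordinates, f2.coordinates)
        assert t1.equals(t2)

    def test_counts_validated(self):
        with pytest.raises(SpecError):
            sy.plant_hbond_geometries(-1, 0, 0)
        with pytest.raises(SpecError):
            sy.plant_hbond_geometries(0, 0, 0)


class TestIsothermGenerator:
    def test_noise_free_max_pressure_is_collapse(self):
        iso = sy.simulate_isotherm(sy.IsothermSpec(collapse_pressure=40.6, noise_sd=0.0))
        assert iso.pi_mN_m.max() == pytest.approx(40.6)

    def test_condensed_branch_extrapolates_to_limiting_area(self):
        spec = sy.IsothermSpec(limiting_area=84.8, noise_sd=0.0)
        iso = sy.simulate_isotherm(spec)
        mask = (iso.pi_mN_m > 0) & (iso.pi_mN_m < spec.collapse_pressure)
        fit = sps.linregress(iso.area_A2[mask], iso.pi_mN_m[mask])
        assert -fit.intercept / fit.slope == pytest.approx(84.8, abs=1e-9)

    def test_mixing_shift_recovered_by_regression(self):
        fracs = [0.0, 0.25, 0.5, 0.75]
        pi_ref = 20.0
        areas = []
        for f in fracs:
            spec = sy.IsothermSpec(mixing_slope=-10.0, mole_fraction=f, noise_sd=0.0, seed=0)
            iso = sy.simulate_isotherm(spec)
            # invert the exact linear branch at the reference pressure
            a0 = 84.8 - 10.0 * f
            rising = (iso.pi_mN_m > 0) & (iso.pi_mN_m < spec.collapse_pressure)
            areas.append(
                np.interp(pi_ref, iso.pi_mN_m[rising], iso.area_A2[rising])
            )
            assert areas[-1] == pytest.approx(a0 - pi_ref / spec.condensed_slope, abs=0.2)
        fit = sps.linregress(fracs, areas)
        assert fit.slope == pytest.approx(-10.0, abs=0.3)

    def test_noise_requires_nonnegative_sd(self):
        with pytest.raises(SpecError):
            sy.IsothermSpec(noise_sd=-0.1)

    def test_determinism(self):
        a = sy.simulate_isotherm(sy.IsothermSpec(noise_sd=0.5, seed=3))
        b = sy.simulate_isotherm(sy.IsothermSpec(noise_sd=0.5, seed=3))
        assert np.array_equal(a.pi_mN_m, b.pi_mN_m)
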