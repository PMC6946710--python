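"""Oligomer photophysics model, stochastic traces and rendered stacks."""

import math

import numpy as np
import pytest
import tifffile

import psafret as p
from psafret.errors import NumericalError
from psafret.image_io import load_rois


def chord_deviation(model, p_on=0.5):
    """How far the ensemble curve sags below its chord at ``p_on``."""
    chord = (1 - p_on) * p.ensemble_anisotropy(0.0, model) + p_on * p.ensemble_anisotropy(
        1.0, model
    )
    return chord - p.ensemble_anisotropy(p_on, model)


class TestClusterAnisotropy:
    def test_single_fluorophore_is_r_mono(self):
        m = p.OligomerModel(n_subunits=3, r_mono=0.3, coupling=5.0)
        assert p.cluster_anisotropy(1, m) == pytest.approx(0.3)

    def test_zero_coupling_is_r_mono(self):
        m = p.OligomerModel(n_subunits=4, r_mono=0.32, coupling=0.0)
        for k in range(1, 5):
            assert p.cluster_anisotropy(k, m) == pytest.approx(0.32)

    def test_dimer_value(self, dimer_model):
        assert p.cluster_anisotropy(2, dimer_model) == pytest.approx(0.35 * 2 / 3, abs=1e-5)

    def test_k_out_of_range(self, dimer_model):
        with pytest.raises(NumericalError):
            p.cluster_anisotropy(3, dimer_model)
        with pytest.raises(NumericalError):
            p.cluster_anisotropy(0, dimer_model)


class TestEnsembleAnisotropy:
    def test_all_off_limit_is_r_mono(self, dimer_model):
        assert p.ensemble_anisotropy(0.0, dimer_model) == pytest.approx(0.35)

    def test_monomer_constant(self, monomer_model):
        for p_on in [0.0, 0.3, 1.0]:
            assert p.ensemble_anisotropy(p_on, monomer_model) == pytest.approx(0.35)

    def test_dimer_is_affine(self, dimer_model):
        r0 = p.ensemble_anisotropy(0.0, dimer_model)
        r1 = p.ensemble_anisotropy(1.0, dimer_model)
        for p_on in np.linspace(0, 1, 21):
            expected = (1 - p_on) * r0 + p_on * r1
            assert p.ensemble_anisotropy(p_on, dimer_model) == pytest.approx(
                expected, abs=1e-12
            )

    @pytest.mark.parametrize("n", range(2, 13))
    @pytest.mark.parametrize("p_on", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_bounded_by_endpoints(self, n, p_on):
        # with r_et <= r_mono the ensemble lies between r_et and r_mono
        m = p.OligomerModel(n_subunits=n, r_mono=0.35, r_et=0.0, coupling=2.0)
        r = p.ensemble_anisotropy(p_on, m)
        assert 0.0 - 1e-12 <= r <= 0.35 + 1e-12

    def test_binomial_weights_normalized(self):
        # a model with r identically 1 in every cluster state integrates to 1
        for n in range(1, 13):
            m = p.OligomerModel(n_subunits=n, r_mono=0.4, r_et=0.4, coupling=3.0)
            for p_on in [0.0, 0.25, 0.5, 0.75, 1.0]:
                assert p.ensemble_anisotropy(p_on, m) == pytest.approx(0.4, abs=1e-12)

    def test_tetramer_sags_below_chord(self):
        m = p.OligomerModel(n_subunits=4, r_mono=0.35, r_et=0.0, d_over_r0=0.8)
        assert chord_deviation(m) > 0

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_chord_deviation_decreases_with_separation(self, n):
        devs = [
            chord_deviation(p.OligomerModel(n_subunits=n, r_mono=0.35, d_over_r0=d))
            for d in [0.5, 0.75, 1.0, 1.25, 1.5]
        ]
        assert all(d >= 0 for d in devs)
        assert all(a >= b for a, b in zip(devs, devs[1:]))


class TestOligomerModel:
    def test_coupling_from_distance(self):
        m = p.OligomerModel(n_subunits=2, d_over_r0=0.8)
        assert m.coupling == pytest.approx(0.8**-6, abs=1e-12)

    def test_inconsistent_coupling_raises(self):
        with pytest.raises(NumericalError):
            p.OligomerModel(n_subunits=2, coupling=1.0, d_over_r0=0.8)

    def test_invalid_ranges(self):
        with pytest.raises(NumericalError):
            p.OligomerModel(n_subunits=0)
        with pytest.raises(NumericalError):
            p.OligomerModel(n_subunits=2, r_mono=0.5)


class TestProjectToChannels:
    def test_isotropic_channels_equal(self):
        for theta in [20.0, 45.0, 67.5]:
            optics = p.OpticsConfig(
                numerical_aperture=math.sin(math.radians(theta)),
                refractive_index=1.0, apply_axelrod=True,
            )
            i_par, g_i_perp = p.project_to_channels(0.0, 6.0, optics)
            assert i_par == pytest.approx(g_i_perp, abs=1e-12)

    def test_mixed_channels_at_60deg(self):
        # (I_z, I_y) = (5, 2), i.e. r = 1/3 and F = 9
        optics = p.OpticsConfig(
            numerical_aperture=math.sin(math.radians(60.0)),
            refractive_index=1.0, apply_axelrod=True,
        )
        i_par, g_i_perp = p.project_to_channels(1 / 3, 9.0, optics)
        assert i_par == pytest.approx(4.34375, abs=1e-6)
        assert g_i_perp == pytest.approx(2.03125, abs=1e-6)

    def test_ideal_channels(self, ideal_optics):
        assert p.project_to_channels(1 / 3, 9.0, ideal_optics) == pytest.approx((5.0, 2.0))


class TestSimulateTrace:
    def test_no_coupling_flat_anisotropy(self, monomer_model, ideal_optics, quiet_camera):
        trace, _ = p.simulate_trace(
            monomer_model, p.SwitchingParams(), quiet_camera, ideal_optics,
            n_oligomers=2000, seed=0,
        )
        keep = trace.par_sub + trace.perp_sub > 0
        r = p.anisotropy(trace.par_sub[keep], trace.perp_sub[keep])
        assert np.allclose(r, 0.35, atol=1e-9)

    def test_no_switching_constant_brightness(self, dimer_model, ideal_optics, quiet_camera):
        trace, _ = p.simulate_trace(
            dimer_model, p.SwitchingParams(p_off_per_frame=0.0, n_frames=10),
            quiet_camera, ideal_optics, n_oligomers=500, seed=0,
        )
        f = p.total_fluorescence(trace.par_sub, trace.perp_sub)
        assert np.allclose(f, f[0])

    def test_noiseless_dimer_recovery(self, dimer_model, ideal_optics, quiet_camera):
        trace, truth = p.simulate_trace(
            dimer_model, p.SwitchingParams(), quiet_camera, ideal_optics,
            n_oligomers=10_000, seed=11,
        )
        result = p.analyze_trace(trace, ideal_optics)
        assert result.drfret == pytest.approx(truth.drfret_true, abs=0.01)

    def test_same_seed_reproduces(self, dimer_model, ideal_optics):
        cam = p.CameraModel()
        args = (dimer_model, p.SwitchingParams(), cam, ideal_optics)
        t1, _ = p.simulate_trace(*args, n_oligomers=100, seed=5)
        t2, _ = p.simulate_trace(*args, n_oligomers=100, seed=5)
        assert np.array_equal(t1.mean_par, t2.mean_par)
        assert np.array_equal(t1.mean_perp, t2.mean_perp)

    def test_ground_truth_consistency(self, dimer_model, ideal_optics):
        _, truth = p.simulate_trace(
            dimer_model, p.SwitchingParams(), p.CameraModel(), ideal_optics,
            n_oligomers=10, seed=0,
        )
        assert truth.r_et0_true == pytest.approx(0.35)
        assert truth.r_et1_true == pytest.approx(p.cluster_anisotropy(2, dimer_model))
        assert truth.drfret_true == pytest.approx(
            p.drfret(truth.r_et0_true, truth.r_et1_true), abs=1e-12
        )


class TestRenderStack:
    def test_zero_signal_background_is_offset(self, monomer_model, ideal_optics, tmp_path):
        cam = p.CameraModel(photons_per_fluor=0.0, offset=100.0)
        scene = p.simulate_scene(
            monomer_model, p.SwitchingParams(n_frames=5), cam, ideal_optics,
            n_oligomers=10, seed=0,
        )
        paths = p.render_stack(scene, p.SceneGeometry(), seed=0, out_dir=tmp_path)
        pages = tifffile.imread(paths["stack"])
        assert pages.mean() == pytest.approx(100.0, abs=0.5)

    def test_same_seed_byte_identical(self, dimer_model, ideal_optics, tmp_path):
        scene = p.simulate_scene(
            dimer_model, p.SwitchingParams(n_frames=8), p.CameraModel(), ideal_optics,
            n_oligomers=1000, seed=2,
        )
        pa = p.render_stack(scene, p.SceneGeometry(), seed=2, out_dir=tmp_path / "a")
        pb = p.render_stack(scene, p.SceneGeometry(), seed=2, out_dir=tmp_path / "b")
        assert pa["stack"].read_bytes() == pb["stack"].read_bytes()

    def test_round_trip_recovers_truth(self, rendered_dimer, ideal_optics):
        par, perp = p.read_stack(rendered_dimer["stack"])
        rois = {r.label: r for r in load_rois(rendered_dimer["roi"])}
        trace = p.extract_trace(par, perp, rois["cell"], rois["background"])
        with pytest.warns(UserWarning):
            result = p.analyze_trace(trace, ideal_optics)
        assert result.drfret == pytest.approx(
            rendered_dimer["truth_data"]["drfret_true"], abs=0.01
        )


def test_end_to_end_recovery_many_seeds(tmp_path):
    """Full render->read->analyze loop stays within +/-0.02 of truth across seeds."""
    model = p.OligomerModel(n_subunits=2, r_mono=0.35, r_et=0.0, coupling=1.0)
    optics = p.OpticsConfig(apply_axelrod=False)
    errors = []
    for seed in range(20):
        scene = p.simulate_scene(
            model, p.SwitchingParams(), p.CameraModel(), optics,
            n_oligomers=10_000, seed=seed,
        )
        paths = p.render_stack(scene, p.SceneGeometry(), seed=seed, out_dir=tmp_path / str(seed))
        par, perp = p.read_stack(paths["stack"])
        rois = {r.label: r for r in load_rois(paths["roi"])}
        trace = p.extract_trace(par, perp, rois["cell"], rois["background"])
        with pytest.warns(UserWarning):
            result = p.analyze_trace(trace, optics)
        errors.append(abs(result.drfret - scene.truth.drfret_true))
    assert max(errors) < 0.02
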