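import json
from pathlib import Path

import pytest

import psafret as p


@pytest.fixture
def dimer_model():
    """Tandem dimer at strong coupling: r(1)=0.35, r(2)=0.35*2/3."""
    return p.OligomerModel(n_subunits=2, r_mono=0.35, r_et=0.0, coupling=1.0)


@pytest.fixture
def monomer_model():
    return p.OligomerModel(n_subunits=1, r_mono=0.35, r_et=0.0, coupling=0.0)


@pytest.fixture
def ideal_optics():
    """No polarization mixing, balanced channels."""
    return p.OpticsConfig(numerical_aperture=1.4, refractive_index=1.515,
                          g_factor=1.0, apply_axelrod=False)


@pytest.fixture
def quiet_camera():
    """Deterministic detector: no shot noise, no read noise, no baseline."""
    return p.CameraModel(photons_per_fluor=200.0, read_noise_sd=0.0,
                         offset=0.0, gain=1.0, shot_noise=False)


@pytest.fixture(scope="session")
def rendered_dimer(tmp_path_factory):
    """One rendered dimer dataset: stack.tif + roi.json + truth.json."""
    out = tmp_path_factory.mktemp("dimer")
    model = p.OligomerModel(n_subunits=2, r_mono=0.35, r_et=0.0, coupling=1.0)
    optics = p.OpticsConfig(apply_axelrod=False)
    scene = p.simulate_scene(model, p.SwitchingParams(), p.CameraModel(), optics,
                             n_oligomers=10_000, seed=7)
    paths = p.render_stack(scene, p.SceneGeometry(), seed=7, out_dir=out)
    paths["truth_data"] = json.loads(Path(paths["truth"]).read_text())
    return paths
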