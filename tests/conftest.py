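from pathlib import Path

import pytest

import cochlea3d as c3
from cochlea3d import phantom as ph
from cochlea3d import pipeline as pl


@pytest.fixture(scope="session")
def default_spec() -> ph.HelixSpec:
    return ph.default_phantom()


@pytest.fixture(scope="session")
def phantom_cloud(default_spec):
    """The study cloud: 4000 points per scala, noise 0.25 x tube radius."""
    cloud, mid = ph.generate_scala_cloud(
        default_spec, 4000, noise_sigma=0.25 * default_spec.tube_radius,
        seed=0)
    return cloud, mid


@pytest.fixture(scope="session")
def fitted_model(default_spec, phantom_cloud):
    cloud, _ = phantom_cloud
    model = c3.init_mirrored_gmm(default_spec, 64, 0.1)
    fitted, trace = c3.fit_gmm(model, cloud,
                               c3.FitConfig(max_iterations=80))
    return fitted, trace


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Two identical default-phantom pipeline runs (determinism witness)."""
    outs = []
    for name in ("runA", "runB"):
        out = tmp_path_factory.mktemp("pipe") / name
        cfg = pl.PipelineConfig(phantom={}, output_dir=str(out), seed=0)
        manifest = c3.run_reconstruction(cfg)
        outs.append((Path(out), manifest))
    return outs
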