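import pytest

from sprayeval.config import RunConfig
from sprayeval.scene import CameraRig, Plot
from sprayeval.synthetic import ScenarioConfig


@pytest.fixture
def rig() -> CameraRig:
    return CameraRig()


@pytest.fixture
def small_scenario() -> ScenarioConfig:
    """Two short plots (one sandy, one peaty) for fast end-to-end tests."""
    plots = (
        Plot(plot_id=1, soil_type="sandy", contains_barley=True, length_m=4.0),
        Plot(plot_id=2, soil_type="peaty", contains_barley=False, length_m=4.0),
    )
    return ScenarioConfig(plots=plots, seed=7, potatoes_per_plot=(8, 12))


@pytest.fixture
def small_run_config() -> RunConfig:
    plots = (
        Plot(plot_id=1, soil_type="sandy", contains_barley=True, length_m=4.0),
        Plot(plot_id=2, soil_type="peaty", contains_barley=False, length_m=4.0),
    )
    return RunConfig(plots=plots, seed=11)
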