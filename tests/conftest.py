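import pytest

from reaimsim import SCENARIO_NAMES, run_grid, scenario_presets


@pytest.fixture(scope="session")
def default_grids():
    """The four scenario sweeps at default parameters on a 21x21 grid."""
    presets = scenario_presets()
    return {name: run_grid(presets[name], 21) for name in SCENARIO_NAMES}
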