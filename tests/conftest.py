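from dataclasses import replace

import pytest

from orbitduel import ViewingCondition, make_preset

INDUCER_PRESETS = ("movie2", "movie3", "movie4", "movie5", "movie6")
ALL_PRESETS = ("movie1",) + INDUCER_PRESETS

CONDITIONS = {
    "fixate": ViewingCondition(mode="fixate", fixation_point=(5.0, 5.0)),
    "pursue_target": ViewingCondition(mode="pursue_target"),
    "pursue_inducer": ViewingCondition(mode="pursue_inducer", inducer_index=0),
}


@pytest.fixture(scope="session")
def presets():
    return {name: make_preset(name) for name in ALL_PRESETS}


def movie2_with_phase(phase0_deg: float):
    """Equal-speed opposite-direction stimulus with an arbitrary inducer phase."""
    stim = make_preset("movie2")
    return replace(stim, inducer_orbit=replace(stim.inducer_orbit, phase0=phase0_deg),
                   name=f"movie2_phase{phase0_deg:g}")
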