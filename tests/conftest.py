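import warnings

import numpy as np
import pytest

from psvsim.archetypes import archetype_spec, tune_archetype
from psvsim.circuit import CircuitParameters, VentilatorConfig
from psvsim.muscle import schedule_breaths
from psvsim.solver import SimulationConfig, simulate

warnings.filterwarnings("ignore", message="lsoda")


@pytest.fixture(scope="session")
def tuned():
    """Tuned parameter sets for all five archetypes (seed 0)."""
    return {name: tune_archetype(archetype_spec(name), seed=0)
            for name in ("healthy", "obese", "ards", "copd", "fibrosis")}


@pytest.fixture(scope="session")
def circuit():
    return CircuitParameters()


@pytest.fixture(scope="session")
def healthy_record(tuned, circuit):
    """Three normal pressure-support breaths on the healthy archetype."""
    vent = VentilatorConfig(PEEP=5.0, Pinsp=7.4)
    rng = np.random.default_rng(7)
    duration = 16.0
    sched = schedule_breaths(15.0, duration, ["normal"] * 3, rng)
    sim = SimulationConfig(duration=duration)
    return simulate(tuned["healthy"], circuit, vent, sched, sim)
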