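"""Shared fixtures.

The session-scoped GC simulations are the expensive objects in this suite;
they are computed once with the shipped default parameters and shared by the
ordering, fraction, maturation and stability tests.
"""

import numpy as np
import pytest

from edisim.gc import GCParams, simulate_gc
from edisim.priming import PrimingParams, simulate_priming
from edisim.regimens import parse_regimen


@pytest.fixture(scope="session")
def gc_params():
    return GCParams()


@pytest.fixture(scope="session")
def priming_params():
    return PrimingParams()


@pytest.fixture(scope="session")
def priming_trajectories(priming_params):
    """Default-parameter priming runs for the three reference regimens."""
    return {
        name: simulate_priming(priming_params, parse_regimen(name), t_end=21.0)
        for name in ("bolus", "2ed", "7ed")
    }


@pytest.fixture(scope="session")
def gc_runs(gc_params):
    """Default-parameter lymph-node runs for the reference regimens.

    2-ED and its 10-day extended-release variant use the 10 replicates of
    the headline comparison; bolus and 7-ED use 5 (they enter only through
    orderings, where replicate noise is far smaller than the contrasts).
    """
    reps = {"bolus": 5, "2ed": 10, "7ed": 5, "2ed-ext:10": 10}
    return {
        name: simulate_gc(
            gc_params, parse_regimen(name), t_end=21.0,
            n_replicates=n, seed=11,
        )
        for name, n in reps.items()
    }


@pytest.fixture(scope="session")
def small_gc_params():
    """Reduced-size GC configuration for cheap structural tests."""
    return GCParams(n_gc=4, gc_capacity=300, seeding_rate=20.0)
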