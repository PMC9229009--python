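import numpy as np
import pytest

from slbqcmd.packing import load_species, mixture_from_fractions
from slbqcmd.simulate import generate_trace, scenario_defaults

SCENARIOS = ("vesicle_layer", "two_step_slb", "one_step_slb", "incomplete_bilayer")


@pytest.fixture(scope="session")
def species():
    return load_species()


@pytest.fixture(scope="session")
def mixtures():
    """The five membrane compositions plus pure PC."""
    return {
        "PC": mixture_from_fractions({"PC": 1.0}),
        "PG": mixture_from_fractions({"PG": 1.0}),
        "9:1 PG/LPG": mixture_from_fractions({"PG": 0.9, "LPG": 0.1}),
        "8:2 PG/LPG": mixture_from_fractions({"PG": 0.8, "LPG": 0.2}),
        "7:3 PG/LPG": mixture_from_fractions({"PG": 0.7, "LPG": 0.3}),
        "6:4 PG/LPG": mixture_from_fractions({"PG": 0.6, "LPG": 0.4}),
    }


@pytest.fixture(scope="session")
def noisefree_runs():
    """Noise-free default trace + params for each scenario (shared, read-only)."""
    runs = {}
    for scen in SCENARIOS:
        p = scenario_defaults(scen)
        runs[scen] = (p, generate_trace(p))
    return runs


@pytest.fixture
def flat_trace():
    """Zero-signal 3-harmonic trace, 20 min at 1 s sampling."""
    from slbqcmd.traces import QCMDTrace

    t = np.arange(0, 20, 1 / 60)
    zero = np.zeros_like(t)
    return QCMDTrace(
        time=t,
        delta_f={n: zero.copy() for n in (3, 7, 11)},
        delta_D={n: zero.copy() for n in (3, 7, 11)},
    )
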