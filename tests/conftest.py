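"""Shared fixtures: the assembled spine network, its resting state, and a
cache of standard stimulated runs reused across tests (they are the
expensive part of the suite)."""

import numpy as np
import pytest

from spinesim import build_network
from spinesim.experiments import plasticity_ratio, pre_equilibrate, run
from spinesim.stimulus import CalciumProtocol, DopamineProtocol


@pytest.fixture(scope="session")
def network():
    return build_network()


@pytest.fixture(scope="session")
def resting_state(network):
    return pre_equilibrate(network)


@pytest.fixture(scope="session")
def standard_runs(network, resting_state):
    """Time courses for the four canonical input conditions (600 s)."""
    out = {}
    for key, ca_amp, da_amp in (
        ("weak", 1.0, 0.0), ("strong", 10.0, 0.0),
        ("da", 0.0, 1.0), ("weak_da", 1.0, 1.0),
    ):
        tc = run(network,
                 CalciumProtocol(ca_amp=ca_amp),
                 DopamineProtocol(da_amp=da_amp),
                 t_end=600.0, y0=resting_state)
        out[key] = tc
    return out


@pytest.fixture(scope="session")
def standard_ratios(standard_runs):
    return {k: plasticity_ratio(tc).ratio for k, tc in standard_runs.items()}


def species_total(network, tc_or_state, names):
    """Sum of concentrations over species names (trajectory or state)."""
    if hasattr(tc_or_state, "names"):
        return sum(tc_or_state[n] for n in names)
    return sum(tc_or_state[network.index[n]] for n in names)


#: Free + complexed phospho-Thr75 DARPP-32 states.
PT75_SPECIES = ("D32_75", "D32_75_137", "D32_34_75", "D32_34_75_137",
                "D32_75_PKAc", "D32_75_137_PKAc")
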