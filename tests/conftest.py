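import numpy as np
import pytest

from ssbkin import prose_parameters, table1_parameters


@pytest.fixture(scope="session")
def table1():
    return table1_parameters()


@pytest.fixture(scope="session")
def prose():
    return prose_parameters()


@pytest.fixture(scope="session")
def ideal_50nM_cycle(table1):
    """Ideal 50 nM incubate -> rinse -> re-incubate trace (calibrated set)."""
    from ssbkin import incubate_rinse_protocol, simulate_protocol
    proto = incubate_rinse_protocol(50.0, t_incubate=300.0, t_rinse=200.0,
                                    t_reincubate=150.0)
    return simulate_protocol(proto, table1)


def rel_err(x, ref):
    return abs(x - ref) / abs(ref)
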