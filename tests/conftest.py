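import numpy as np
import pytest

from patchkit import (
    CohortSpec,
    GroupSpec,
    SynapticParams,
    standard_neuron,
    vc_step_protocol,
)


@pytest.fixture(scope="session")
def std_params():
    return standard_neuron()


@pytest.fixture(scope="session")
def leak_only_params():
    return standard_neuron(g_Na_nS=0.0, g_Kfast_nS=0.0, g_Kslow_nS=0.0)


@pytest.fixture(scope="session")
def vc_protocol():
    return vc_step_protocol()


def tiny_cohort_spec(master_seed: int = 1, duration_s: float = 5.0) -> CohortSpec:
    """2 groups × 2 lines × 3 cells with short gap-free traces: the demo
    cohort used by the pipeline tests."""
    syn = SynapticParams(duration_s=duration_s)
    return CohortSpec(
        groups=[
            GroupSpec("control", n_lines=2, cells_per_line=3, synaptic=syn),
            GroupSpec(
                "case", n_lines=2, cells_per_line=3, synaptic=syn,
                effects={"g_Na_scale": 0.5, "rate_scale": 0.5, "amp_scale": 0.6},
            ),
        ],
        master_seed=master_seed,
    )


@pytest.fixture()
def demo_spec():
    return tiny_cohort_spec()
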