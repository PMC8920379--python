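import hypothesis
import numpy as np
import pytest

from hemobind import simulate as sim

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("default")


@pytest.fixture
def quench_series():
    """Noiseless Stern-Volmer titration with per-point inner filtering."""
    absorb = [(0.02 * i, 0.03 * i) for i in range(8)]
    return sim.gen_quenching_titration(ksv=4.1272e4, inner_filter_a=absorb,
                                       temperature=293.0)


@pytest.fixture
def iv_profile_dense():
    """Dense noiseless i.v. one-compartment profile (>= 5 half-lives)."""
    times = np.arange(0.0, 18.0 + 1e-9, 0.01)
    return sim.gen_pk_profile("iv_1cpt", {"c0": 2.833, "ke": 0.221},
                              times, dose=2.5)
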