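import numpy as np
import pytest
from hypothesis import settings

import expertchoice as ec

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_spec(level_counts, coding="dummy", constraints=(), interactions=()):
    """Small throwaway spec with factors f1, f2, ... and levels L0, L1, ..."""
    codings = [coding] * len(level_counts) if isinstance(coding, str) else coding
    factors = tuple(
        ec.Factor(
            name=f"f{i + 1}",
            levels=tuple(f"L{j}" for j in range(n)),
            coding=c,
        )
        for i, (n, c) in enumerate(zip(level_counts, codings))
    )
    return ec.ExperimentSpec(
        decision_label="toy decision",
        factors=factors,
        constraints=tuple(constraints),
        interactions=tuple(interactions),
    )


@pytest.fixture(scope="session")
def nec_spec():
    return ec.load_nec_spec()


@pytest.fixture(scope="session")
def nec_fit():
    return ec.load_nec_fit()


@pytest.fixture(scope="session")
def nec_profiles():
    return ec.load_nec_example_profiles()


@pytest.fixture(scope="session")
def nec_design(nec_spec):
    # moderate search effort: the acceptance-scale studies reuse this design
    return ec.generate_design(nec_spec, 35, seed=1, n_starts=3, max_passes=10)


@pytest.fixture
def binary2_spec():
    return make_spec([2, 2])


@pytest.fixture
def binary3_spec():
    return make_spec([3, 2], coding=["dummy", "dummy"])


@pytest.fixture
def mixed_spec():
    # dummy 3-level, linear 3-level, dummy 2-level
    return make_spec([3, 3, 2], coding=["dummy", "linear", "dummy"])
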