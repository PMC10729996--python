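import numpy as np
import pytest

import irontraffic as it


@pytest.fixture(scope="session")
def bundle():
    return it.load_bundle()


@pytest.fixture(scope="session")
def W(bundle):
    return bundle.state("W")


@pytest.fixture(scope="session")
def Y(bundle):
    return bundle.state("Y")


@pytest.fixture(scope="session")
def D(bundle):
    return bundle.state("D")


@pytest.fixture(scope="session")
def case1(bundle):
    return bundle.crm("case1")


@pytest.fixture(scope="session")
def printed_profiles(bundle):
    """The published (rounded) per-state concentration columns."""
    return {lab: it.ConcentrationProfile.from_dict(
        bundle.config["states"][lab]["concentrations"])
        for lab in ("W", "Y", "D")}


@pytest.fixture(scope="session")
def k_table(bundle):
    return {rid: tuple(bundle.state(lab).params.k[rid] for lab in "WYD")
            for rid in it.filter_uniqueness(bundle.states)}


@pytest.fixture(scope="session")
def conc_table(bundle):
    return {c: tuple(bundle.state(lab).profile[c] for lab in "WYD")
            for c in it.COMPONENTS}


def random_profiles(n, seed=0, scale=1000.0):
    rng = np.random.RandomState(seed)
    return scale * rng.rand(n, 8)
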