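import numpy as np
import pytest

from jpcgied import (
    JPCSample,
    JPCScheme,
    JointGIEDParams,
    load_jute,
    parse_scheme,
    simulate_jpc,
)


@pytest.fixture(scope="session")
def toy_sample() -> JPCSample:
    """Tiny hand-checkable JPC sample: m=n=2, k=2, one withdrawal per line."""
    scheme = JPCScheme(m=2, n=2, k=2, R=(1, 1))
    return JPCSample(
        w=np.array([1.0, 2.0]),
        z=np.array([1, 0]),
        s=np.array([1, 0]),
        t=np.array([0, 1]),
        scheme=scheme,
    )


@pytest.fixture(scope="session")
def jute():
    """The two jute breaking-strength samples, divided by 1000."""
    return load_jute()


@pytest.fixture(scope="session")
def table1_scheme() -> JPCScheme:
    return parse_scheme("(0(4),25,0(15))", m=20, n=25, k=20)


@pytest.fixture(scope="session")
def std_params() -> JointGIEDParams:
    """The simulation-study generating truth."""
    return JointGIEDParams(1.0, 1.0, 0.5)


@pytest.fixture(scope="session")
def sim_sample(std_params, table1_scheme) -> JPCSample:
    return simulate_jpc(std_params, table1_scheme, seed=42)


def make_datasets(params, schemes, n_per_scheme, seed0):
    """Seeded JPC datasets with both lines represented (k1, k2 > 0)."""
    out = []
    for j, scheme in enumerate(schemes):
        got = 0
        seed = seed0 + 1000 * j
        while got < n_per_scheme:
            d = simulate_jpc(params, scheme, seed)
            seed += 1
            if d.k1 > 0 and d.k2 > 0:
                out.append(d)
                got += 1
    return out
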