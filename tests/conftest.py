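import numpy as np
import pytest

import tacklecoach as tc


@pytest.fixture(scope="session")
def sample_stream() -> tc.ImuStream:
    """The packaged four-reading printed-dump log, parsed."""
    return tc.load_sample_stream()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_unit_quaternion(rng: np.random.Generator) -> tc.Quaternion:
    v = rng.normal(size=4)
    return tc.quat_normalize(tc.Quaternion.from_array(v))


@pytest.fixture()
def random_quats(rng) -> list[tc.Quaternion]:
    return [random_unit_quaternion(rng) for _ in range(50)]
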