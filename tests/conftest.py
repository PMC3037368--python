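import numpy as np
import pytest

from alazip.records import ProteinRecord
from alazip.synthetic import ZipperSpec, generate_dimer_fixture, generate_zipper


@pytest.fixture
def group2_zipper():
    """Planted group-II preset: 6 Ala-core heptads, fully complementary."""
    record, truth = generate_zipper(ZipperSpec(n_heptads=6, seed=17))
    return record, truth


@pytest.fixture
def parallel_dimer():
    dimer, info = generate_dimer_fixture(ZipperSpec(n_heptads=6, seed=17))
    return dimer, info


@pytest.fixture
def random_records():
    """Seeded random sequences over the full alphabet, lengths <= 200."""
    rng = np.random.default_rng(2024)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    records = []
    for k in range(30):
        n = int(rng.integers(30, 201))
        seq = "".join(rng.choice(alphabet, size=n))
        records.append(ProteinRecord(id=f"rand{k}", sequence=seq))
    return records


def rigid_transform(rng):
    """A random proper rotation + translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.normal(scale=20.0, size=3)
    return rot, t
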