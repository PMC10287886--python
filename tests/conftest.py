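import numpy as np
import pytest

from rbqe.core import FeatureDatabase, ImageRecord
from rbqe.synthetic import SyntheticSpec, gen_feature_db, table1_database, table1_fixture


@pytest.fixture(scope="session")
def table1():
    """The worked mean-expansion example: member vectors + expected mean."""
    return table1_fixture()


@pytest.fixture()
def table1_db():
    return table1_database()


@pytest.fixture(scope="session")
def random_db():
    """A 50-record, 4-class random database with occasional exact ties."""
    rng = np.random.default_rng(1234)
    records = []
    for i in range(50):
        label = f"class_{i % 4:02d}"
        vec = rng.integers(0, 4, size=8).astype(float)  # small ints force ties
        records.append(ImageRecord(id=f"r{i:02d}", class_label=label, features=vec))
    return FeatureDatabase(records)


@pytest.fixture(scope="session")
def separated_db():
    """Well-separated Gaussian clusters: separation/sigma = 50."""
    spec = SyntheticSpec(
        n_classes=4, class_sizes=(15, 12, 11, 10), dim=16,
        separation=50.0, sigma=1.0, seed=42,
    )
    return gen_feature_db(spec)


def brute_force_distance(x, y):
    """Per-component sum-of-squares loop (independent of the package)."""
    total = 0.0
    for a, b in zip(x, y, strict=True):
        total += (a - b) ** 2
    return total ** 0.5


def brute_force_ranking(probe, db, candidate_ids=None):
    """Distance-then-stable-sort oracle returning ids in rank order."""
    pool = [rid for rid in db.ids if candidate_ids is None or rid in set(candidate_ids)]
    dists = {rid: brute_force_distance(probe, db[rid].features) for rid in pool}
    return sorted(pool, key=lambda rid: (dists[rid], db.index_of(rid)))
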