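import numpy as np
import pandas as pd
import pytest
import skbio
from hypothesis import HealthCheck, settings

from gutcore.metadata import SampleMetadata
from gutcore.simulate import SimulationDesign, generate_dataset
from gutcore.table import OtuTable

settings.register_profile(
    "unit",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("unit")


@pytest.fixture
def small_table() -> OtuTable:
    frame = pd.DataFrame(
        [[5, 0, 3, 1], [2, 4, 0, 0], [0, 1, 7, 2]],
        index=["s1", "s2", "s3"],
        columns=["o1", "o2", "o3", "o4"],
    )
    return OtuTable(frame, marker="V12")


@pytest.fixture
def four_tip_tree() -> skbio.TreeNode:
    # ((A:1,B:2):0.5,(C:3,D:1):0.25); total length 7.75
    return skbio.TreeNode.read(["((A:1,B:2):0.5,(C:3,D:1):0.25);"])


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    rows = {}
    for sp, genus, tribe, diet, origin, n in [
        ("sp1", "g1", "t1", "zooplanktivore", "wild", 3),
        ("sp2", "g2", "t1", "scale-eater", "wild", 3),
        ("sp3", "g3", "t2", "omnivore", "wild", 2),
    ]:
        for k in range(n):
            rows[f"{sp}_{k}"] = {
                "host_species": sp,
                "host_genus": genus,
                "host_tribe": tribe,
                "diet": diet,
                "origin": origin,
            }
    return SampleMetadata(pd.DataFrame.from_dict(rows, orient="index"))


@pytest.fixture(scope="session")
def default_dataset():
    """One default-design synthetic dataset shared across tests."""
    return generate_dataset(SimulationDesign(seed=0))


def random_count_table(rng: np.random.Generator, n_samples=6, n_otus=10, marker="V12"):
    counts = rng.integers(0, 20, size=(n_samples, n_otus))
    frame = pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"o{j}" for j in range(n_otus)],
    )
    # keep rows non-empty
    frame.iloc[:, 0] += 1
    return OtuTable(frame, marker)
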