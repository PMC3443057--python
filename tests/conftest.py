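import numpy as np
import pytest

from coremod.io_prep import (
    ExpressionStudy,
    GeneSetCollection,
    InteractionNetwork,
)


@pytest.fixture
def tiny_study():
    """3 genes x 4 samples, two per class, no missing values."""
    return ExpressionStudy(
        genes=["g1", "g2", "g3"],
        samples=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [2.0, 4.0, 6.0, 8.0],
                [4.0, 3.0, 2.0, 1.0],
            ]
        ),
        labels={"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
        name="tiny",
    )


@pytest.fixture
def six_sample_study():
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(1, 7)]
    samples = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
    return ExpressionStudy(
        genes=genes,
        samples=samples,
        values=rng.standard_normal((6, 6)),
        labels={s: s[0].upper() for s in samples},
        name="six",
    )


@pytest.fixture
def small_collection():
    return GeneSetCollection(
        sets={"GO_X": {"g1", "g2", "g3"}, "GO_Y": {"g1", "g4", "g5", "g6"}},
        source="fixture",
    )


@pytest.fixture
def small_interactions():
    return InteractionNetwork.from_edge_pairs(
        [("g1", "g2"), ("g2", "g3"), ("g1", "g4"), ("g4", "g5")]
    )
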