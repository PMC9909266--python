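import numpy as np
import pandas as pd
import pytest

from germdiv import BandMatrix, ColorTable, TraitTable


@pytest.fixture
def band_matrix_small() -> BandMatrix:
    """4 genotypes x 6 bands over two primers; fully observed."""
    calls = np.array(
        [
            [1, 0, 1, 1, 0, 1],
            [1, 1, 0, 1, 0, 1],
            [0, 1, 1, 0, 1, 1],
            [0, 0, 1, 0, 1, 1],
        ],
        dtype=float,
    )
    bands = [f"b{i}" for i in range(1, 7)]
    primers = {b: ("P1" if i < 3 else "P2") for i, b in enumerate(bands)}
    return BandMatrix(["g1", "g2", "g3", "g4"], bands, primers, calls)


@pytest.fixture
def trait_table_small() -> TraitTable:
    values = pd.DataFrame(
        {
            "height": [10.0, 12.0, 30.0, 33.0],
            "leaves": [5.0, 6.0, 11.0, 12.0],
            "petal_color": ["pink", "pink", "white", "white"],
            "leaf_pattern": ["plain", "silver", "silver", "plain"],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return TraitTable(
        values,
        {
            "height": "quantitative",
            "leaves": "quantitative",
            "petal_color": "qualitative",
            "leaf_pattern": "qualitative",
        },
        {"petal_color": ["pink", "white"], "leaf_pattern": ["plain", "silver"]},
    )


@pytest.fixture
def color_table_small() -> ColorTable:
    rows = []
    triplets = {
        "g1": {"slip": (80.0, 20.0, 5.0), "eye": (30.0, 45.0, -10.0)},
        "g2": {"slip": (78.0, 22.0, 6.0), "eye": (28.0, 47.0, -12.0)},
        "g3": {"slip": (95.0, 2.0, 1.0), "eye": (60.0, 10.0, 3.0)},
    }
    for g, organs in triplets.items():
        for organ, (L, a, b) in organs.items():
            rows.append({"genotype": g, "organ": organ, "L": L, "a": a, "b": b})
    return ColorTable(pd.DataFrame(rows))
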