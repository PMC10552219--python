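import numpy as np
import pandas as pd
import pytest

from immunospat.phenotyping import MARKERS


def make_cells(rows, sample_id="S1"):
    """Build a cell table from (x, y, phenotype) triples with marker calls
    consistent with the default gates."""
    marker_map = {
        "tumor": {"CK"},
        "cytotoxic T": {"CD3", "CD8"},
        "helper T": {"CD3"},
        "Treg": {"CD3", "FoxP3"},
        "B": {"CD20"},
        "macrophage": {"CD68"},
        "NK": {"CD56"},
    }
    recs = []
    for i, (x, y, ph) in enumerate(rows):
        rec = {"sample_id": sample_id, "cell_id": f"c{i}", "x_um": x, "y_um": y}
        for m in MARKERS:
            rec[m] = 1 if m in marker_map.get(ph, set()) else 0
        rec["phenotype"] = ph
        recs.append(rec)
    return pd.DataFrame(recs)


@pytest.fixture
def two_type_cells():
    """Nine cells, tumor and cytotoxic T mixed in a 200x200 window."""
    return make_cells([
        (10, 10, "tumor"), (50, 60, "tumor"), (150, 40, "tumor"),
        (120, 160, "tumor"), (30, 30, "cytotoxic T"), (55, 65, "cytotoxic T"),
        (160, 45, "cytotoxic T"), (110, 150, "cytotoxic T"), (190, 190, "tumor"),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_pattern(rng, n_max=50, types=("A", "B"), size=300.0):
    """Random two-type pattern for oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    xy = rng.uniform(0, size, size=(n, 2))
    labels = rng.choice(types, size=n)
    df = make_cells([(x, y, "tumor") for x, y in xy])
    df["phenotype"] = labels
    return df
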