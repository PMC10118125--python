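import numpy as np
import pandas as pd
import pytest

TIME_POINTS = ["0h", "1h", "3h", "6h", "veg"]


def make_fraction_table(records):
    """Build a canonical fraction-quant DataFrame from tuples of
    (protein, time, replicate, fraction, abundance, n_peptides, coverage)."""
    return pd.DataFrame(
        records,
        columns=[
            "protein_id",
            "time_point",
            "replicate",
            "fraction",
            "abundance",
            "n_peptides",
            "coverage",
        ],
    )


@pytest.fixture
def tiny_fraction_csv(tmp_path):
    """Smallest complete table: 2 proteins x 1 time x 1 rep x 2 fractions."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "protein_id,time_point,replicate,fraction,abundance,n_peptides,coverage\n"
        "A,0h,1,supernatant,5.0,3,0.5\n"
        "A,0h,1,pellet,5.0,3,0.5\n"
        "B,0h,1,supernatant,2.0,4,0.4\n"
        "B,0h,1,pellet,6.0,4,0.4\n"
    )
    return path


@pytest.fixture
def complete_table():
    """3 proteins, 2 time points, 2 replicates, all detected."""
    rows = []
    for pid, p in [("A", 0.8), ("B", 0.5), ("C", 0.2)]:
        for tp in ["0h", "1h"]:
            for rep in [1, 2]:
                rows.append((pid, tp, rep, "supernatant", 100 * (1 - p), 5, 0.5))
                rows.append((pid, tp, rep, "pellet", 100 * p, 5, 0.5))
    return make_fraction_table(rows)
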