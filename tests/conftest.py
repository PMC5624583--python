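import numpy as np
import pandas as pd
import pytest


def make_quantity_table(rows):
    """Build a quantity table from (sample, series, day, gene, role, q) tuples."""
    return pd.DataFrame(
        rows, columns=["sample_id", "series", "day", "gene", "role", "quantity"]
    )


@pytest.fixture
def worked_example_table():
    """Two-sample series with reference quantities {100,300} and {200,200}.

    Reference A has fractions {0.5, 1.5} and reference B {1.0, 1.0}, so the
    factors are {0.75, 1.25}; the target {75, 125} normalizes to {100, 100}.
    """
    return make_quantity_table(
        [
            ("s1", "S", 0, "refA", "reference", 100.0),
            ("s2", "S", 3, "refA", "reference", 300.0),
            ("s1", "S", 0, "refB", "reference", 200.0),
            ("s2", "S", 3, "refB", "reference", 200.0),
            ("s1", "S", 0, "tgt", "target", 75.0),
            ("s2", "S", 3, "tgt", "target", 125.0),
        ]
    )


def random_quantity_table(seed, n_series=2, n_samples=4, n_refs=2, n_targets=2):
    """Random positive-quantity table satisfying all preconditions."""
    rng = np.random.default_rng(seed)
    rows = []
    for si in range(n_series):
        series = f"S{si}"
        for di in range(n_samples):
            sample = f"{series}_{di}"
            for g in range(n_refs):
                rows.append(
                    (sample, series, di, f"ref{g}", "reference",
                     float(rng.uniform(10, 1000)))
                )
            for g in range(n_targets):
                rows.append(
                    (sample, series, di, f"tgt{g}", "target",
                     float(rng.uniform(0, 1000)))
                )
    return make_quantity_table(rows)
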