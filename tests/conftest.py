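"""Shared fixtures: tiny hand-built matrices and designs."""

import numpy as np
import pandas as pd
import pytest

from proxidia.containers import DesignTable, PeptideMatrix


def build_matrix(values, samples=None, proteins=None, sequences=None, **flags):
    """Construct a PeptideMatrix from a 2D list (NaN = missing)."""
    arr = np.asarray(values, dtype=float)
    n, m = arr.shape
    samples = samples or [f"CA_{i + 1}" for i in range((m + 1) // 2)] + [
        f"DN_{i + 1}" for i in range(m // 2)
    ]
    sequences = sequences or [f"PEPTIDE{i}K" for i in range(n)]
    proteins = proteins or [f"P{i:03d}" for i in range(n)]
    ann = pd.DataFrame({"sequence": sequences, "protein": proteins})
    ann["gene"] = [f"G{p}" for p in ann["protein"]]
    for key, vals in flags.items():
        ann[key] = vals
    X = pd.DataFrame(arr, columns=samples)
    return PeptideMatrix(ann, X)


@pytest.fixture
def design_3v3():
    return DesignTable(
        pd.DataFrame(
            {
                "sample": ["CA_1", "CA_2", "CA_3", "DN_1", "DN_2", "DN_3"],
                "group": ["CA"] * 3 + ["DN"] * 3,
                "replicate": [1, 2, 3, 1, 2, 3],
            }
        ),
        "CA",
        "DN",
    )


@pytest.fixture
def design_2v2():
    return DesignTable(
        pd.DataFrame(
            {
                "sample": ["CA_1", "CA_2", "DN_1", "DN_2"],
                "group": ["CA", "CA", "DN", "DN"],
                "replicate": [1, 2, 1, 2],
            }
        ),
        "CA",
        "DN",
    )
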