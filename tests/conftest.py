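import numpy as np
import pandas as pd
import pytest

from interactome import IntensityMatrix


def make_matrix(values: dict[str, list], scale: str = "linear") -> IntensityMatrix:
    """Build a small matrix from {column_name: values}; NaN marks missing."""
    df = pd.DataFrame(values, dtype=float)
    df.index = pd.Index([f"P{i}" for i in range(len(df))], name="protein_id")
    return IntensityMatrix(values=df, scale=scale)


@pytest.fixture
def small_log2_matrix() -> IntensityMatrix:
    """4 proteins x (surface, endosomal, control) x 2 replicates, log2 scale, complete."""
    rng = np.random.default_rng(7)
    cols = [f"{g}_{r}" for g in ("surface", "endosomal", "control") for r in (1, 2)]
    df = pd.DataFrame(rng.normal(25, 2, size=(4, 6)), columns=cols)
    df.index = pd.Index([f"P{i}" for i in range(4)], name="protein_id")
    return IntensityMatrix(values=df, scale="log2")
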