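import numpy as np
import pandas as pd
import pytest

from gsinv.dataio import ExpressionMatrix, GeneSet


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """6 genes x (3 normal + 3 tumor), deterministic positive values."""
    rng = np.random.default_rng(42)
    samples = ["N1", "N2", "N3", "T1", "T2", "T3"]
    genes = [f"g{i}" for i in range(6)]
    data = pd.DataFrame(rng.lognormal(1.0, 0.5, size=(6, 6)),
                        index=genes, columns=samples)
    cond = pd.Series(["normal"] * 3 + ["tumor"] * 3, index=samples)
    return ExpressionMatrix(data, cond)


@pytest.fixture
def focal_pair(small_matrix) -> GeneSet:
    return GeneSet("focal", ("g0", "g2", "g4"))
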