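import numpy as np
import pandas as pd
import pytest

from dietmap.simulate import SimulationConfig, generate_expression
from dietmap.study import ExpressionStudy


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_study(default_config):
    """One simulated study + truth, shared across read-only tests."""
    return generate_expression(default_config)


@pytest.fixture()
def tiny_study() -> ExpressionStudy:
    """Hand-built 4-gene study: 2 tissues x 2 groups x 3 replicates."""
    rng = np.random.default_rng(5)
    tissues = ["liver", "muscle"]
    groups = ["beef", "herring"]
    rows = []
    for t in tissues:
        for g in groups:
            for r in range(1, 4):
                rows.append((f"{t}_{g}_r{r}", t, g, r))
    meta = pd.DataFrame(rows, columns=["sample_id", "tissue", "group", "replicate"]
                        ).set_index("sample_id")
    expr = pd.DataFrame(rng.normal(7, 1, size=(4, len(meta))),
                        index=pd.Index([f"G{i}" for i in range(4)], name="gene_id"),
                        columns=meta.index)
    genes = pd.DataFrame({"chromosome": ["1", "1", "2", "X"],
                          "position_bp": [100, 50, 10, 5]},
                         index=expr.index)
    return ExpressionStudy(expr, meta, genes)
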