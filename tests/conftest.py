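import numpy as np
import pandas as pd
import pytest

import coregrn as cg


@pytest.fixture
def tiny_panel():
    """Two probes → two entities, constant intensities 4 (TU) and 8 (AN)."""
    patients = ["P1", "P2", "P3", "P4"]
    tu = pd.DataFrame(4.0, index=["p1", "p2"], columns=patients)
    an = pd.DataFrame(8.0, index=["p1", "p2"], columns=patients)
    probe_map = pd.DataFrame(
        {
            "probe_id": ["p1", "p2"],
            "entity_id": ["TF1", "g1"],
            "entity_class": ["TF", "gene"],
        }
    )
    return cg.ExpressionPanel(tu=tu, an=an, probe_map=probe_map)


@pytest.fixture(scope="session")
def default_bundle():
    """Default-condition synthetic panel: 96 patients, 50% decoys, seed 42."""
    config = cg.SyntheticConfig(seed=42)
    panel, candidates, truth = cg.generate_panel(config)
    return config, panel, candidates, truth


@pytest.fixture(scope="session")
def default_ratios(default_bundle):
    _, panel, _, _ = default_bundle
    alpha = cg.compute_alpha(panel)
    return cg.merge_probes(cg.compute_ratios(panel, alpha), panel.probe_map)


def ratio_matrix(values: dict[str, list[float]]) -> cg.RatioMatrix:
    """Entity-level RatioMatrix straight from profile lists (test helper)."""
    df = pd.DataFrame(values).T
    df.columns = [f"P{i}" for i in range(df.shape[1])]
    return cg.RatioMatrix(values=df, alpha=1.0)


def correlated_pair(rng: np.random.Generator, r: float, n: int):
    """x, y with population Pearson correlation r."""
    z = rng.standard_normal(n)
    x = z
    y = r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    return x, y
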