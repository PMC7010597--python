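import numpy as np
import pandas as pd
import pytest

from genecascade.data_model import ExpressionMatrix, GeneSet
from genecascade.rank_activity import RankScoreMatrix
from genecascade.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A scaled-down but fully wired synthetic configuration."""
    return SyntheticConfig(
        n_genes=400,
        n_samples=5,
        n_pathways=8,
        pathway_size_range=(6, 10),
        m=2,
        delta=3.0,
        sigma=1.0,
        frac_dysregulated=0.25,
        n_key_genes=3,
        n_drivers=2,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return generate_bundle(small_cfg)


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    """4 genes x 1 sample with distinct values 9 > 5 > 3 > 1."""
    return ExpressionMatrix(
        pd.DataFrame({"s1": [9.0, 5.0, 3.0, 1.0]}, index=["g1", "g2", "g3", "g4"])
    )


@pytest.fixture
def toy_scores(toy_expression):
    from genecascade.rank_activity import rank_transform

    return rank_transform(toy_expression)


def make_scores(values: np.ndarray, genes, samples) -> RankScoreMatrix:
    return RankScoreMatrix(pd.DataFrame(values, index=genes, columns=samples))


@pytest.fixture
def two_function_sets():
    return [GeneSet("top", frozenset({"g1", "g2"})), GeneSet("bottom", frozenset({"g3", "g4"}))]
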