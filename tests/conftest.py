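"""Shared fixtures: small synthetic datasets with planted ground truth."""

import numpy as np
import pytest

from floralnet.differential import normalize
from floralnet.io import ExpressionMatrix
from floralnet.synthetic import SyntheticConfig, generate_expression, generate_go_table

STAGES8 = [f"S{i}" for i in range(1, 9)]


def make_matrix(profiles: dict[str, list[float]], calls: dict[str, str] | None = None):
    """ExpressionMatrix from literal per-gene signal profiles."""
    genes = list(profiles)
    n_stages = len(next(iter(profiles.values())))
    signal = np.array([profiles[g] for g in genes], dtype=float)
    call = np.full((len(genes), n_stages), "P", dtype="U1")
    if calls:
        for g, pattern in calls.items():
            call[genes.index(g), :] = list(pattern)
    return ExpressionMatrix(
        gene_ids=genes,
        stage_labels=[f"S{i + 1}" for i in range(n_stages)],
        signal=signal,
        call=call,
    )


@pytest.fixture(scope="session")
def archetype_fixture():
    """900 genes, 9 archetypes × 100, noise_sd 0.25, no cores or absentees."""
    cfg = SyntheticConfig(
        n_genes=900,
        n_core=0,
        n_flower_cores=0,
        partners_per_core=0,
        absent_fraction=0.0,
        noise_sd=0.25,
        seed=1,
    )
    matrix, truth = generate_expression(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def default_fixture():
    """The full default synthetic dataset: cores, partners, GO labels."""
    cfg = SyntheticConfig(seed=1)
    matrix, truth = generate_expression(cfg)
    go = generate_go_table(truth, cfg)
    return cfg, matrix, truth, go


@pytest.fixture(scope="session")
def default_normalized(default_fixture):
    _, matrix, _, _ = default_fixture
    return normalize(matrix)
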