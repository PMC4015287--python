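import numpy as np
import pytest

from mirpu.score_data import InteractionKey, PUDataset, ScoreTable, standardize_scores
from mirpu.synthetic import PRESETS, SyntheticSpec, generate


def make_table(scores, present=None, names=None):
    scores = np.asarray(scores, dtype=float)
    if present is None:
        present = np.ones_like(scores, dtype=bool)
    n, s = scores.shape
    keys = [InteractionKey(f"miR-{i}", f"G{i}") for i in range(n)]
    names = names or [f"alg{j}" for j in range(s)]
    return ScoreTable(keys, list(names), scores, np.asarray(present, bool))


@pytest.fixture(scope="session")
def tiny_benchmark():
    """One standardized tiny-preset dataset with its hidden truth."""
    overrides, _, _ = PRESETS["tiny"]
    data, truth, true_c = generate(SyntheticSpec(seed=42, **overrides))
    table = standardize_scores(data.table)
    return PUDataset(table, data.labeled), truth, true_c
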