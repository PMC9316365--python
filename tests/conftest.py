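import numpy as np
import pandas as pd
import pytest

from ispip import ScoreTable


def make_table(n=200, k=3, seed=0, prevalence=0.2, signal=2.0, protein_ids=("P1",)):
    """Labelled score table where each predictor is label + noise, squashed
    into [0,1]; signal 0 gives pure noise channels."""
    rng = np.random.default_rng(seed)
    frames = []
    for pid in protein_ids:
        y = (rng.random(n) < prevalence).astype(int)
        cols = {
            f"x{j + 1}": 1 / (1 + np.exp(-(signal * (y - 0.5) + rng.standard_normal(n))))
            for j in range(k)
        }
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": pid,
                    "chain": "A",
                    "resnum": np.arange(1, n + 1),
                    "icode": "",
                    **cols,
                    "label": y,
                }
            )
        )
    return ScoreTable(pd.concat(frames, ignore_index=True))


@pytest.fixture
def small_table():
    return make_table(n=300, seed=1)


@pytest.fixture
def multi_protein_table():
    return make_table(n=120, seed=2, protein_ids=[f"P{i}" for i in range(8)])
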