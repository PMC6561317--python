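import pandas as pd
import pytest

from mempis.reaction_db import load_network


TOY_TABLE = (
    "reaction_id\tequation\tecs\tmodules\tpathways\n"
    "R1\tA => B\t1.1.1.1\tM00001\tmap00010\n"
    "R2\tB => C\t\tM00001\t\n"
    "R3\tA => C\t\tM00002\t\n"
)


@pytest.fixture
def toy_net(tmp_path):
    """Three reactions R1: A->B, R2: B->C, R3: A->C; R1 carries EC 1.1.1.1."""
    path = tmp_path / "toy.tsv"
    path.write_text(TOY_TABLE)
    return load_network(path, currency_blacklist=())


@pytest.fixture
def toy_table(tmp_path):
    path = tmp_path / "toy.tsv"
    path.write_text(TOY_TABLE)
    return path


@pytest.fixture
def small_counts():
    """Two-group count matrix with one clearly shifted EC."""
    data = {
        "A-control-1": [100, 50, 10, 200],
        "A-control-2": [110, 55, 12, 190],
        "A-control-3": [90, 45, 9, 210],
        "A-dry-1": [400, 52, 11, 205],
        "A-dry-2": [420, 48, 10, 195],
        "A-dry-3": [380, 50, 12, 200],
    }
    return pd.DataFrame(data, index=["1.1.1.1", "2.2.2.2", "3.3.3.3", "4.4.4.4"])


@pytest.fixture
def small_design():
    rows = []
    for trt in ("control", "dry"):
        for rep in (1, 2, 3):
            rows.append(
                {
                    "sample": f"A-{trt}-{rep}",
                    "site": "A",
                    "treatment": trt,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)
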