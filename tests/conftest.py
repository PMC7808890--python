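import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cbar.data_model import Dataset, Transaction, build_bitmap_index
from cbar.knowledge_base import Intervention, KnowledgeBase
from cbar.synthetic_cohort import fixture_a


@pytest.fixture(scope="session")
def fixture_a_dataset() -> Dataset:
    return fixture_a()


@pytest.fixture(scope="session")
def fixture_a_index(fixture_a_dataset):
    return build_bitmap_index(fixture_a_dataset)


@pytest.fixture()
def abc_kb() -> KnowledgeBase:
    """Full-vocabulary KB over FIXTURE-A items: A→I1, B→I2, C uncompiled."""
    return KnowledgeBase(
        allowed_items=frozenset({"A", "B", "C"}),
        interventions={
            "A": (Intervention("I1", "reduce A exposure", "A"),),
            "B": (Intervention("I2", "address B", "B"),),
        },
    )


def random_dataset(rng: np.random.Generator, n_max=300, n_items_max=12, positive_rate=0.3):
    """A random transaction dataset for oracle-equivalence checks."""
    n = int(rng.integers(10, n_max + 1))
    n_items = int(rng.integers(3, n_items_max + 1))
    items = [f"i{j}" for j in range(n_items)]
    p = rng.uniform(0.1, 0.6, size=n_items)
    txs = []
    for i in range(n):
        members = frozenset(it for it, pi in zip(items, p) if rng.random() < pi)
        outcome = int(rng.random() < positive_rate)
        txs.append(Transaction(i, members, outcome))
    if not any(t.outcome == 1 for t in txs):  # guarantee a non-empty S_w
        txs[0] = Transaction(txs[0].instance_id, txs[0].items, 1)
    return Dataset(tuple(txs), interesting_values=(1,))
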