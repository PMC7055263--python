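import numpy as np
import pytest

from esec import blockworld, relations
from esec.app import canonical_models, load_all_fixtures


@pytest.fixture(scope="session")
def canonical_tables():
    """Canonical (variant-free) ESEC per class, extracted from the
    scripted world."""
    out = {}
    for action in blockworld.ACTIONS:
        traj = blockworld.generate_action(
            action, variant_params=blockworld.VariantParams.canonical()
        )
        out[action] = relations.extract_esec(traj, action_label=action)
    return out


@pytest.fixture(scope="session")
def fixture_tables():
    """The packaged canonical fixture files."""
    return load_all_fixtures()


@pytest.fixture(scope="session")
def singleton_models():
    return canonical_models()


@pytest.fixture(scope="session")
def dataset_tables():
    """The full labeled corpus (10 classes x 30 variants), extracted."""
    trajs = blockworld.generate_dataset(seed=0)
    return [
        relations.extract_esec(t, action_label=t.action_label) for t in trajs
    ]


def random_table(rng: np.random.Generator, n_cols: int | None = None):
    """A random (not necessarily physically meaningful) valid-symbol table
    for similarity-measure tests."""
    from esec.core import ALPHABET, CHANNELS, ESECTable, N_PAIRS

    n_cols = n_cols or int(rng.integers(2, 8))  # C0 plus 1..6 event columns
    cells = np.empty((N_PAIRS, len(CHANNELS), n_cols), dtype=object)
    for c, channel in enumerate(CHANNELS):
        symbols = sorted(ALPHABET[channel])
        for i in range(N_PAIRS):
            for j in range(n_cols):
                cells[i, c, j] = symbols[int(rng.integers(len(symbols)))]
    return ESECTable(cells, np.arange(n_cols, dtype=float))
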