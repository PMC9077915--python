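import numpy as np
import pandas as pd
import pytest

from refstab.io_tables import CtTable


def make_ct_table(ct_rows, gene_ids, tissues=None, animals=None, reps=None):
    """Build a CtTable from a list of per-sample Ct rows."""
    n = len(ct_rows)
    ids = [f"s{i + 1}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "tissue": tissues if tissues is not None else ["t1"] * n,
            "animal": animals if animals is not None else [f"a{i + 1}" for i in range(n)],
            "technical_replicate": reps if reps is not None else [1] * n,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    ct = pd.DataFrame(ct_rows, index=meta.index, columns=gene_ids, dtype=float)
    return CtTable(ct, meta)


def random_ct_table(rng, n_genes=5, n_samples=8):
    """Random complete Ct table: gene baselines + sample effects + noise."""
    baseline = rng.uniform(15, 30, size=n_genes)
    sample_effect = rng.normal(0, 1.0, size=n_samples)
    noise = rng.normal(0, rng.uniform(0.05, 0.8, size=n_genes), size=(n_samples, n_genes))
    ct = baseline[None, :] + sample_effect[:, None] + noise
    return make_ct_table(ct.tolist(), [f"g{j + 1}" for j in range(n_genes)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def three_gene_table():
    """The worked 3-gene, 4-sample example used across geNorm tests."""
    return make_ct_table(
        [[20, 25, 30], [21, 26, 30], [20, 25, 31], [21, 26, 31]],
        ["G1", "G2", "G3"],
    )
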