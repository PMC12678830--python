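import pandas as pd
import pytest

import shutoffseq as ss


@pytest.fixture(scope="session")
def small_experiment() -> ss.ShutoffExperiment:
    """An 800-gene simulated experiment shared across tests (read-only)."""
    return ss.ShutoffExperiment.simulate(ss.default_config(n_genes=800, seed=1))


@pytest.fixture(scope="session")
def small_results(small_experiment) -> ss.ShutoffResults:
    return small_experiment.fit()


def make_contrast_table(genes, fdr, l2fc, status=None) -> pd.DataFrame:
    """Hand-built contrast table with just the columns the classifiers read."""
    status = status or ["ok"] * len(genes)
    return pd.DataFrame(
        {
            "base_mean": [100.0] * len(genes),
            "l2fc_mle": l2fc,
            "l2fc_shrunk": l2fc,
            "se": [0.1] * len(genes),
            "pvalue": fdr,
            "fdr": fdr,
            "status": status,
            "flagged": [False] * len(genes),
        },
        index=pd.Index(genes, name="gene_id"),
    )


class FakeContrast:
    """Duck-typed stand-in for de.ContrastResult in rule-level tests."""

    def __init__(self, table):
        self.table = table


@pytest.fixture
def contrast_factory():
    def build(genes, fdr, l2fc, status=None):
        return FakeContrast(make_contrast_table(genes, fdr, l2fc, status))

    return build
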