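import numpy as np
import pandas as pd
import pytest

from pairde import SynthConfig, generate_bundle
from pairde.io import ExpressionMatrix


def make_matrix(values, conditions=None, pair_ids=None, symbols=None, biotypes=None):
    """Build a small ExpressionMatrix from a 2D array.

    Default design: columns alternate tumor/normal, one pair per two columns.
    """
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    probe_ids = [f"PR{i:03d}" for i in range(n)]
    sample_ids = [f"S{j:02d}" for j in range(m)]
    if conditions is None:
        conditions = ["tumor", "normal"] * (m // 2)
    if pair_ids is None:
        pair_ids = [f"P{j // 2 + 1:02d}" for j in range(m)]
    if symbols is None:
        symbols = [f"G{i:03d}" for i in range(n)]
    if biotypes is None:
        biotypes = ["mRNA"] * n
    vdf = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    probes = pd.DataFrame({"gene_symbol": symbols, "biotype": biotypes}, index=vdf.index)
    design = pd.DataFrame({"condition": conditions, "pair_id": pair_ids},
                          index=pd.Index(sample_ids, name="sample"))
    return ExpressionMatrix(values=vdf, probes=probes, design=design)


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(n_probes=800, n_de=60, n_sets=40, n_enriched_sets=2,
                       n_modules=2, module_size=10, n_hubs=2, hub_degree=12,
                       background_edges=120, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """(matrix, truth, collection, interactions, qpcr) on a compact cohort."""
    return generate_bundle(small_config)
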