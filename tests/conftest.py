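import numpy as np
import pandas as pd
import pytest

import nersig as ns


@pytest.fixture(scope="session")
def small_panel():
    """A compact simulated knockdown panel with planted truth (shared across
    tests; treat as read-only)."""
    cfg = ns.PanelSimConfig(seed=7, n_genes=400, n_core_de=40, n_private_de=10)
    return ns.simulate_isogenic_panel(cfg)


@pytest.fixture(scope="session")
def panel_signature(small_panel):
    mat, design, truth = small_panel
    results = {g: ns.moderated_de(mat, design, g) for g in design.case_groups}
    genes = ns.select_consensus_genes(results)
    sig = ns.build_signature(results, genes)
    return results, sig, truth


@pytest.fixture()
def toy_matrix():
    data = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4),
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ns.ExpressionMatrix(data, log_scale=True)
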