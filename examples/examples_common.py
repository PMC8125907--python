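"""Shared helper for the example scripts: a quickly derived demo signature."""

import nersig as ns


def demo_signature(seed: int = 7) -> ns.GeneSignature:
    cfg = ns.PanelSimConfig(seed=seed, n_genes=600, n_core_de=60, n_private_de=15)
    mat, design, _ = ns.simulate_isogenic_panel(cfg)
    results = {line: ns.moderated_de(mat, design, line) for line in design.case_groups}
    genes = ns.select_consensus_genes(results)
    return ns.build_signature(results, genes)
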