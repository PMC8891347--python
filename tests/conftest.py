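import numpy as np
import pytest

import hybridpanel as hp


@pytest.fixture(scope="session")
def small_panel():
    """A small reference dataset exercising every generator feature."""
    model = hp.PopulationModel(
        n_loci=600,
        seed=11,
        n_linked_pairs=8,
        n_homeolog_like=30,
        missing_rate=0.05,
    )
    panel, records = hp.simulate_rad_dataset(model)
    return panel


@pytest.fixture(scope="session")
def designed_panel():
    """Full-size designed panel: 3000-locus reference, filter chain, top 342."""
    model = hp.PopulationModel(n_loci=3000, seed=1)
    panel, _ = hp.simulate_rad_dataset(model)
    candidates, report, stats = hp.design_panel(panel)
    top = candidates.head(342)
    sub = panel.subset_loci(list(top.index))
    freqs = hp.estimate_reference_frequencies(sub)
    return {
        "panel": panel,
        "candidates": candidates,
        "top": top,
        "sub": sub,
        "freqs": freqs,
        "report": report,
        "stats": stats,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
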