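"""Shared fixtures: two simulated datasets reused across test modules."""

import numpy as np
import pytest

from powerdeg import generate


@pytest.fixture(scope="session")
def small_sim():
    """Small matrix with strong, easily detectable DEGs (fast DE runs)."""
    return generate(
        n_genes=400,
        n_ko=6,
        n_wt=6,
        deg_fraction=0.15,
        fc_band=(1.5, 2.5),
        mean_distribution=(np.log(200.0), 1.2),
        seed=11,
    )


@pytest.fixture(scope="session")
def null_sim():
    """Matrix with no true DEGs at all."""
    return generate(
        n_genes=400,
        n_ko=6,
        n_wt=6,
        deg_fraction=0.0,
        mean_distribution=(np.log(200.0), 1.2),
        seed=13,
    )


@pytest.fixture(scope="session")
def study_sim():
    """Desk-scale analogue of a deep weak-effect case-control experiment.

    2,000 genes, 10% true DEGs with fold changes 1.1-1.5, 12 KO vs 14 WT.
    """
    return generate(
        n_genes=2000,
        n_ko=12,
        n_wt=14,
        deg_fraction=0.10,
        fc_band=(1.1, 1.5),
        mean_distribution=(np.log(300.0), 1.8),
        seed=5,
    )
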