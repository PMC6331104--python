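"""Shared fixtures: small synthetic panels and screen results."""

import numpy as np
import pytest

from toxrank.de import DEResult
from toxrank.simulate import SimulationConfig, simulate_panel


SMALL_CFG = SimulationConfig(
    n_genes=300,
    n_compounds=6,
    n_toxic_compounds=4,
    n_planted=30,
    seed=11,
    off_target_range=(10, 40),
)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated screen shared by read-only tests."""
    panels, truth = simulate_panel(SMALL_CFG)
    return panels, truth


def make_results(r2s, ps, selected, genes=None):
    """Build DEResult lists for ranking tests."""
    n = len(r2s)
    genes = genes or [f"g{i}" for i in range(n)]
    return [
        DEResult(
            gene=genes[i],
            passed_global=bool(selected[i]),
            global_q=0.001 if selected[i] else 0.5,
            adjusted_p=float(ps[i]),
            r2=float(r2s[i]),
            n_coef=16,
            has_significant_coef=bool(selected[i]),
            selected=bool(selected[i]),
        )
        for i in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
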