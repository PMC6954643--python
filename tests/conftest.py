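import numpy as np
import pandas as pd
import pytest

from cnmtf.simdata import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_bundle():
    """A small stratified study used across module tests (not the standard fixture)."""
    return simulate_bundle(
        SimConfig(
            m_subjects=120,
            n_snvs=60,
            n_genes=8,
            n_causal=6,
            effect_size=1.0,
            confound_strength=0.3,
            seed=11,
        )
    )


@pytest.fixture()
def annotations_frame():
    return pd.DataFrame(
        {
            "snv_id": ["rs1", "rs2", "rs3", "rs4", "rs5"],
            "gene": ["g1", "g1", "g2", "g2", "g3"],
            "position": [101, 102, 201, 202, 301],
            "impact_class": ["high", "low", "modifier", "moderate", "low"],
            "predicted_deleterious": [False, False, True, False, False],
            "known_association": [False, False, False, False, True],
        }
    )
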