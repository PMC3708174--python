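import numpy as np
import pandas as pd
import pytest

from mirmech import (
    ExpressionMatrix,
    MatureMiRNA,
    SimulationConfig,
    SiteSpec,
)
from mirmech.synthdata import make_interaction


TOY_MIRNA = MatureMiRNA("toy", "UAUGCAAGCAUCGAUCGAUCGG")
# seed m2-m7 = AUGCAA, rc = UUGCAU; rc(m2-m8) = CUUGCAU


@pytest.fixture
def toy_mirna():
    return TOY_MIRNA


@pytest.fixture
def counts_matrix():
    data = pd.DataFrame(
        {
            "S1_r1": [10.0, 40.0, 50.0],
            "S1_r2": [30.0, 60.0, 110.0],
            "S2_r1": [5.0, 20.0, 25.0],
        },
        index=pd.Index(["P1", "P2", "P3"], name="protein"),
    )
    return ExpressionMatrix(data, scale="counts")


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast 4-miRNA / 30-gene study with one gene per mechanism family."""
    planted = [
        make_interaction("miR-001", "G0001", "decay_only",
                         site_spec=SiteSpec("8mer", "3UTR")),
        make_interaction("miR-002", "G0002", "translation_only",
                         site_spec=SiteSpec("8mer", "3UTR", "high")),
        make_interaction("miR-003", "G0003", "both_strong",
                         site_spec=SiteSpec("7mer-m8", "3UTR")),
        make_interaction("miR-004", "G0004", "both_weak"),
        make_interaction("miR-001", "G0005", "decay_compensated",
                         site_spec=SiteSpec("8mer", "3UTR", "low")),
        make_interaction("miR-002", "G0006", "translation_compensated",
                         site_spec=SiteSpec("8mer", "ORF")),
    ]
    kwargs = dict(n_mirnas=4, n_genes=30, planted_interactions=planted,
                  utr5_len=120, orf_len=240, utr3_len=300,
                  n_decoy_bindings=20, seed=seed)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
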