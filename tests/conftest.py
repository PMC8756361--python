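"""Shared fixtures: small synthetic studies, panels and cohorts."""

import numpy as np
import pandas as pd
import pytest

from casediff.ldsc import LDScorePanel
from casediff.simulate import SimConfig, make_paired_gwas, simulate_reference


def make_study(n=6, seed=0, chrom="1"):
    """Small valid sumstats frame with non-palindromic SNVs."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(n)],
        "CHR": chrom, "BP": 1000 * (np.arange(n) + 1),
        "A1": "A", "A2": "G",
        "EAF": rng.uniform(0.1, 0.35, n).round(3),
        "BETA": rng.normal(0, 0.1, n).round(4),
        "SE": np.full(n, 0.05),
        "P": rng.uniform(0.01, 0.99, n).round(4),
        "N_CAS": 1000, "N_CON": 1000,
    })


@pytest.fixture(scope="session")
def linear_panel():
    """LD-score panel with scores spanning [1, 50] over 1000 SNVs."""
    M = 1000
    l = np.linspace(1.0, 50.0, M)
    return LDScorePanel(
        table=pd.DataFrame({"SNP": [f"s{j}" for j in range(M)], "L2": l}), M=M)


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale simulation conditions used by the fast unit tests."""
    return SimConfig(
        m_snvs=300, block_size=5, within_block_r2=0.2, maf_range=(0.05, 0.5),
        h2_shared=0.25, h2_specific=0.1, K_scz=0.05, trs_fraction=0.25,
        n_trs_cases=150, n_nontrs_cases=150, n_controls_1=150, n_controls_2=150,
        n_validation=120, n_reference=300, seed=7)


@pytest.fixture(scope="session")
def tiny_reference(tiny_config):
    return simulate_reference(tiny_config)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    """One full paired-GWAS simulation at desk scale."""
    return make_paired_gwas(tiny_config)
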