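"""Shared fixtures: synthetic genomes, truths and derived LDSC matrices.

Session-scoped where generation is expensive so that many tests can reuse
one simulated study. All randomness is seeded; nothing here reads or writes
outside pytest's tmp dirs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pygsem.ldsc import build_S_V
from pygsem.simulate import (LDStructure, TruthModel, simulate_sumstats,
                             simulate_true_effects)
from pygsem.sumstats import SumstatsTable

TRAITS_11 = ["adhd", "anx", "asd", "mdd", "ptsd",
             "alc", "can", "smk", "bip", "scz", "lone"]


def three_cluster_truth(n_traits: int = 11, n: float = 50_000,
                        factor_corr: np.ndarray | None = None) -> TruthModel:
    """Three genetic clusters (5 + 3 + 2 indicators) plus loneliness on cluster 1."""
    std_load = np.zeros((11, 3))
    std_load[0:5, 0] = [0.60, 0.65, 0.50, 0.75, 0.70]
    std_load[5:8, 1] = [0.55, 0.60, 0.65]
    std_load[8:10, 2] = [0.70, 0.75]
    std_load[10, 0] = 0.66
    if factor_corr is None:
        factor_corr = np.array([[1.0, 0.45, 0.35],
                                [0.45, 1.0, 0.30],
                                [0.35, 0.30, 1.0]])
    h2 = np.array([0.236, 0.079, 0.118, 0.089, 0.050,
                   0.050, 0.070, 0.090, 0.170, 0.412, 0.042])
    return TruthModel.from_standardized(
        std_load[:n_traits], factor_corr, h2[:n_traits],
        np.full(n_traits, n), trait_names=TRAITS_11[:n_traits])


def ld_scores_frame(ld: LDStructure) -> pd.DataFrame:
    return pd.DataFrame({"SNP": ld.snp_ids, "CHR": ld.chromosome,
                         "L2": ld.ld_scores})


def ld_ref_frame(ld: LDStructure) -> pd.DataFrame:
    return pd.DataFrame({"SNP": ld.snp_ids, "CHR": ld.chromosome,
                         "BP": ld.position, "BLOCK": ld.block_index,
                         "R2": np.repeat(ld.within_block_r2, ld.block_sizes)})


@pytest.fixture(scope="session")
def ld_50k() -> LDStructure:
    """A 22-chromosome genome with ~50k SNPs in variable LD blocks."""
    return LDStructure.regular(snps_per_chr=2273, n_chrom=22)


@pytest.fixture(scope="session")
def ld_small() -> LDStructure:
    """A light genome (~5.5k SNPs) for tests that only need structure."""
    return LDStructure.regular(snps_per_chr=250, n_chrom=22)


@pytest.fixture(scope="session")
def study_3cluster(ld_50k):
    """One full simulated 11-trait study plus its LDSC matrices."""
    truth = three_cluster_truth()
    eff = simulate_true_effects(truth, ld_50k, polygenicity=1.0, seed=11)
    tabs = simulate_sumstats(eff, truth, ld_50k, seed=12, qc_fail_frac=0.0,
                             palindromic_frac=0.0)
    tables = [SumstatsTable(t, name=n) for t, n in zip(tabs, truth.trait_names)]
    lds = ld_scores_frame(ld_50k)
    gc_odd_psy = build_S_V(tables[:10], lds, subset="odd_chr")
    gc_even = build_S_V(tables, lds, subset="even_chr")
    return {"truth": truth, "ld": ld_50k, "effects": eff, "tables": tables,
            "ld_scores": lds, "gc_odd_psy": gc_odd_psy, "gc_even": gc_even}


@pytest.fixture(scope="session")
def pair_study(ld_50k):
    """Two traits, h2 = {0.3, 0.1}, rg = 0.6, N = 20,000 — LDSC recovery target."""
    truth = TruthModel.from_standardized(
        std_loadings=[[np.sqrt(0.6)], [np.sqrt(0.6)]], factor_corr=[[1.0]],
        trait_h2=[0.3, 0.1], sample_sizes=[20_000, 20_000],
        trait_names=["t1", "t2"])
    eff = simulate_true_effects(truth, ld_50k, polygenicity=1.0, seed=3)
    tabs = simulate_sumstats(eff, truth, ld_50k, seed=4, qc_fail_frac=0.0,
                             palindromic_frac=0.0)
    tables = [SumstatsTable(t, name=n) for t, n in zip(tabs, truth.trait_names)]
    return {"truth": truth, "tables": tables, "ld_scores": ld_scores_frame(ld_50k)}
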