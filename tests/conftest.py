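"""Shared fixtures: a desk-scale synthetic cohort generated once per session.

The small cohort (2 x 1 Mb genome, 60 cells/condition) keeps unit tests in
the seconds range; acceptance-scale fixtures live in test_acceptance.py.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epihet.config import PipelineConfig
from epihet.io import GeneAnnotation
from epihet.simulate import (
    SimulationConfig,
    build_truth,
    simulate_cells,
    simulate_expression,
    truth_peaks,
)


@pytest.fixture(scope="session")
def small_sim_cfg() -> SimulationConfig:
    return SimulationConfig(
        genome={"chr1": 1_000_000, "chr2": 1_000_000},
        n_cells_per_condition=60,
        mean_depth=1_500.0,
        n_genes=400,
        module_n_peaks=20,
        n_qc_fail_per_mode=2,
        n_cn_segments_per_chrom=5,
        amplicon=("chr1", 0, 300_000, "MET", 4),
        blacklist=(("chr1", 600_000, 620_000), ("chr2", 600_000, 620_000)),
    )


@pytest.fixture(scope="session")
def small_truth(small_sim_cfg):
    return build_truth(small_sim_cfg, seed=1)


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    fragments, labels = simulate_cells(small_truth, seed=2)
    return fragments, labels


@pytest.fixture(scope="session")
def small_expression(small_truth):
    return simulate_expression(small_truth, seed=3)


@pytest.fixture(scope="session")
def small_peaks(small_truth) -> pd.DataFrame:
    return truth_peaks(small_truth)


@pytest.fixture(scope="session")
def small_blacklist(small_sim_cfg) -> pd.DataFrame:
    return pd.DataFrame(list(small_sim_cfg.blacklist), columns=["chrom", "start", "end"])


@pytest.fixture(scope="session")
def small_annotation(small_truth) -> GeneAnnotation:
    return GeneAnnotation(small_truth.genes[["symbol", "chrom", "tss", "strand"]])


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def amplicon_cohort():
    """CN-isolation experiment: conditions identical except the planted
    CN=4 amplicon (equal base rates, no modules, no state drift)."""
    cfg = SimulationConfig(
        genome={"chr1": 1_000_000, "chr2": 1_000_000},
        n_cells_per_condition=100,
        mean_depth=1_500.0,
        n_genes=200,
        module_boost=1.0,
        module_n_peaks=5,
        state_change_fraction=0.0,
        cn_probs=(0.0, 1.0, 0.0, 0.0, 0.0),
        transitional_fraction=0.0,
        n_qc_fail_per_mode=0,
        n_cn_segments_per_chrom=3,
        amplicon=("chr1", 0, 300_000, "MET", 4),
        blacklist=(("chr1", 600_000, 620_000),),
    )
    truth = build_truth(cfg, seed=11)
    fragments, labels = simulate_cells(truth, seed=12)
    return truth, fragments, labels
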