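"""Shared simulation fixtures (session-scoped: the heavy ones run once)."""

from __future__ import annotations

import numpy as np
import pytest

from mirqtl import adjust as adj
from mirqtl import gwas as gw
from mirqtl.synthetic import (
    DecoyEqtl,
    PlantedQtl,
    SimulationConfig,
    simulate_dataset,
)


def small_config(seed: int = 7, **kwargs) -> SimulationConfig:
    """A 400-cow, two-chromosome configuration for fast unit tests."""
    defaults = dict(
        seed=seed,
        n_animals=400,
        n_sires=12,
        n_dams=200,
        n_chromosomes=2,
        chrom_length_bp=10_000_000,
        variants_per_chrom=800,
        n_wavenumbers=60,
        n_herds=8,
        n_test_days=4,
        n_expression_animals=260,
        expression_overlap=62,
        planted_qtl=[
            PlantedQtl("1", 3_000_000, 0, "coding", 0.10, "MODERATE", "GFAT1"),
            PlantedQtl("1", 8_000_000, 1, "expression_mediated", 0.10, "OTHER",
                       "GPROE1"),
            PlantedQtl("2", 5_000_000, 2, "coding", 0.10, "LOW_SPLICE_REGION",
                       "GLAC1"),
        ],
        decoy_eqtl=[
            DecoyEqtl("2", 5_300_000, "GDEC1", away_from_pos=5_000_000),
        ],
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = small_config()
    return cfg, simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """The study-scale default simulation: 2,000 cows, 3 x 5,000 variants."""
    cfg = SimulationConfig(seed=7)
    return cfg, simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_adjusted(default_sim):
    """Adjusted composition traits plus study-cow genotype subset."""
    cfg, (genotypes, pedigree, records, expression, annotations, truth) = default_sim
    adjusted, vc = adj.adjust_traits(records, ["FP", "LP", "PP"])
    study = genotypes.subset_animals(list(adjusted["animal"]))
    return adjusted, vc, study


@pytest.fixture(scope="session")
def default_scanner(default_adjusted):
    adjusted, _, study = default_adjusted
    panel = gw.build_grm(study, study.vids[::5])
    return gw.GwasScanner(study, panel, gw.GwasConfig(n_traits=3))
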