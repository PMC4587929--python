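"""Shared fixtures: synthetic libraries at several scales.

The survey-scale library (205 species / 1332 barcodes) is expensive
enough to build once per session; tests treat it as read-only.
"""

from __future__ import annotations

import pytest

from barcode_audit import pairwise_matrix, simulate_library
from barcode_audit.library import BarcodeLibrary, BarcodeRecord
from barcode_audit.simulate import DeepSplitSpec, SharedPairSpec, SimulationConfig

SESSION_SEED = 11


@pytest.fixture(scope="session")
def survey_sim():
    """Default survey-scale synthetic library with ground truth."""
    return simulate_library(SimulationConfig(seed=SESSION_SEED))


@pytest.fixture(scope="session")
def survey_dm(survey_sim):
    return pairwise_matrix(survey_sim.library)


@pytest.fixture(scope="session")
def small_sim():
    """Small library with one of each engineered feature."""
    cfg = SimulationConfig(
        seed=SESSION_SEED,
        n_species=14,
        total_specimens=90,
        n_singletons=3,
        deep_splits=(
            DeepSplitSpec(4.0, 6, 2),
            DeepSplitSpec(3.0, 8, 1),
            DeepSplitSpec(4.14, 6, 3),
        ),
        shared_pair=SharedPairSpec(),
    )
    return simulate_library(cfg)


@pytest.fixture(scope="session")
def small_dm(small_sim):
    return pairwise_matrix(small_sim.library)


@pytest.fixture(scope="session")
def gapped_sim():
    """Cleanly gapped library: no deep splits, no haplotype sharing."""
    cfg = SimulationConfig(
        seed=SESSION_SEED,
        n_species=15,
        total_specimens=80,
        n_singletons=2,
        deep_splits=(),
        shared_pair=None,
    )
    return simulate_library(cfg)


@pytest.fixture(scope="session")
def gapped_dm(gapped_sim):
    return pairwise_matrix(gapped_sim.library)


def make_library(entries) -> BarcodeLibrary:
    """entries: iterable of (id, species, sequence[, taxonomy, locality])."""
    recs = []
    for e in entries:
        recs.append(BarcodeRecord(*e))
    return BarcodeLibrary(tuple(recs))


@pytest.fixture
def toy_library():
    """Two 2-specimen species, 120 bp, one diagnostic difference block."""
    base = "ACGT" * 30
    var = base[:-8] + "GTCAGTCA"
    return make_library(
        [
            ("q1", "Alpha one", base),
            ("q2", "Alpha one", base),
            ("q3", "Beta two", var),
            ("q4", "Beta two", var),
        ]
    )
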