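"""Shared fixtures: designs and simulated experiments built at test time."""

import numpy as np
import pandas as pd
import pytest

from synstarr import acgt_core_design, acgt_flank_design
from synstarr.association import BarcodeMap
from synstarr.quantify import apply_min_reads
from synstarr.simulate import (
    SimulationConfig,
    barcode_count_matrix,
    draw_ground_truth,
    simulate_counts,
)


@pytest.fixture(scope="session")
def core_design():
    return acgt_core_design()


@pytest.fixture(scope="session")
def flank_design():
    return acgt_flank_design()


def truth_barcode_map(truth, barcode_counts) -> BarcodeMap:
    """Oracle barcode map taken straight from simulator ground truth.

    Keeps collision-free barcodes only, with the simulated DNA counts as
    association read counts; used to test quantification independently of
    the association stage.
    """
    per_bc = truth.pairs["barcode"].value_counts()
    unique = truth.pairs[truth.pairs["barcode"].map(per_bc) == 1]
    entries = pd.DataFrame({
        "barcode": unique["barcode"].to_numpy(),
        "key": unique["key"].to_numpy(),
        "n_reads": barcode_counts.loc[unique["barcode"], "dna"].to_numpy(),
    })
    return BarcodeMap(entries=entries, min_pair_reads=10,
                      min_barcodes_per_variant=5)


def simulate_experiment(design, **kwargs):
    """Simulate counts and return (truth, barcode map, filtered matrix)."""
    config = SimulationConfig(**kwargs)
    truth = draw_ground_truth(design, config)
    matrix = barcode_count_matrix(simulate_counts(truth, config))
    bc_map = truth_barcode_map(truth, matrix)
    counts = apply_min_reads(matrix.loc[bc_map.entries["barcode"]], 5)
    return truth, bc_map, counts


@pytest.fixture(scope="session")
def null_experiment(flank_design):
    """500 variants, no condition effects; used by several modules."""
    return simulate_experiment(flank_design, seed=11, n_variants=500,
                               n_barcodes_per_variant_mean=10,
                               frac_enhancing=0.0, frac_blunting=0.0)
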