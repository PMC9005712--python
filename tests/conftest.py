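import dendropy
import numpy as np
import pytest

from rablhic.genome import Binning
from rablhic.hic_core import BinnedContactMap, balance_matrix
from rablhic.synthetic import (
    SyntheticGenomeConfig,
    simulate_contact_map,
    simulate_tracks,
    simulate_truth,
)

# 5-taxon mosquito-like topology: outgroup albimanus; (coluzzii, merus)
# sister pair; stephensi joins them; atroparvus next.
FIVE_TAXON_NEWICK = (
    "((((coluzzii:10,merus:10):10,stephensi:20):20,atroparvus:40):60,albimanus:100):0;"
)


@pytest.fixture
def five_taxon_tree():
    return dendropy.Tree.get(data=FIVE_TAXON_NEWICK, schema="newick")


def make_tree():
    return dendropy.Tree.get(data=FIVE_TAXON_NEWICK, schema="newick")


@pytest.fixture(scope="session")
def small_plain_config():
    """Two small chromosomes, no Rabl/plaid structure."""
    return SyntheticGenomeConfig(
        n_chroms=2,
        chrom_length=5_000_000,
        rabl_strength=1.0,
        cen_tel_multiplier=1.0,
        compartment_affinity=1.0,
        tad_enrichment=1.0,
    )


@pytest.fixture(scope="session")
def small_plain_map(small_plain_config):
    truth = simulate_truth(small_plain_config, 11)
    cmap = simulate_contact_map(small_plain_config, truth, 12)
    return cmap, truth


@pytest.fixture(scope="session")
def rabl_map():
    """Default full-structure Rabl genome (50 Mb, 25 kb bins), balanced."""
    cfg = SyntheticGenomeConfig()
    truth = simulate_truth(cfg, 21)
    cmap = simulate_contact_map(cfg, truth, 22)
    bal = balance_matrix(cmap, bad_bin_cov_frac=0.0)
    tracks = simulate_tracks(cfg, truth, 23)
    return bal, truth, tracks


def uniform_map(n_chroms=2, bins_per_chrom=20, bin_size=10_000, value=5.0):
    binning = Binning(
        tuple(f"c{i}" for i in range(n_chroms)),
        (bins_per_chrom * bin_size,) * n_chroms,
        bin_size,
    )
    counts = np.full((binning.n_bins, binning.n_bins), float(value))
    return BinnedContactMap(binning, counts)
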