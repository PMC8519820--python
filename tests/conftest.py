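import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ldscaffold.popvar_io import AccessionPanel, GenotypeMatrix, SiteRecord
from ldscaffold.simpop import SimConfig, simulate_population


def make_site(calls, contig="c1", pos=100, ref="A", alts=("G",), depths=None, total_depth=None):
    return SiteRecord(
        contig=contig,
        pos=pos,
        ref_allele=ref,
        alt_alleles=tuple(alts),
        calls=np.asarray(calls, dtype=np.int8),
        depths=None if depths is None else np.asarray(depths),
        total_depth=total_depth,
    )


def make_matrix(sites_by_contig, n_accessions, contig_lengths=None):
    panel = AccessionPanel(tuple(f"a{i}" for i in range(n_accessions)))
    if contig_lengths is None:
        contig_lengths = {
            c: max(s.pos for s in recs) + 1000 for c, recs in sites_by_contig.items()
        }
    return GenotypeMatrix(panel=panel, sites=sites_by_contig, contig_lengths=contig_lengths)


@pytest.fixture(scope="session")
def small_sim():
    """A small but non-trivial simulated genome shared across tests."""
    cfg = SimConfig(
        seed=7,
        n_chromosomes=2,
        chromosome_length=1_500_000,
        n_founders=6,
        n_accessions=30,
        variant_density=3.0,
        recombination_rate=4.0,
        contig_length_mean=350_000,
        contig_length_sd=80_000,
        contig_length_min=100_000,
    )
    return simulate_population(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
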