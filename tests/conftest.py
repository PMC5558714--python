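import numpy as np
import pytest

from lincscan import simulate
from lincscan.models import GeneLocus, TranscriptModel


@pytest.fixture(scope="session")
def sim_config():
    return simulate.SimConfig(seed=11)


@pytest.fixture(scope="session")
def annotation(sim_config):
    return simulate.generate_annotation(sim_config)


@pytest.fixture(scope="session")
def expression(sim_config, annotation):
    loci, _ = annotation
    return simulate.generate_expression(sim_config, loci)


@pytest.fixture(scope="session")
def genotypes(sim_config):
    return simulate.generate_genotypes(sim_config)


def random_transcript(rng, tid="t", chrom="chr1", max_start=100_000,
                      n_exons=None, gene_id=None):
    """A random valid transcript on a toy chromosome."""
    if n_exons is None:
        n_exons = int(rng.integers(1, 5))
    start = int(rng.integers(0, max_start))
    exons = []
    pos = start
    for _ in range(n_exons):
        size = int(rng.integers(40, 400))
        exons.append((pos, pos + size))
        pos += size + int(rng.integers(50, 500))
    return TranscriptModel(id=tid, chrom=chrom, strand="+", exons=exons,
                           fpkm=float(rng.uniform(0, 10)),
                           coverage=float(rng.uniform(0, 20)),
                           cpc_score=float(rng.uniform(-3, 3)),
                           gene_id=gene_id or tid)


def random_locus(rng, lid, chrom="chr1", max_start=200_000, biotype="protein_coding"):
    start = int(rng.integers(0, max_start))
    return GeneLocus(id=lid, chrom=chrom, start=start,
                     end=start + int(rng.integers(200, 5000)), biotype=biotype)
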