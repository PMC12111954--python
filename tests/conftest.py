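import numpy as np
import pytest

from synfrac.model import Gene, Genome, HomologyHit
from synfrac.pipeline import reference_analysis
from synfrac.simulate import SimParams, run_simulation, synthetic_homology_rows


def make_gene(gid, chrom="1", start=100, end=None, species="sp", strand="+", rank=-1,
              ordinal=None):
    return Gene(id=gid, species=species, chromosome=chrom,
                chrom_ordinal=ordinal if ordinal is not None else int(chrom),
                start=start, end=end if end is not None else start + 50,
                strand=strand, rank=rank)


def make_genome(species, placements):
    """placements: list of (gene_id, chrom, start)."""
    genes = [make_gene(g, chrom=c, start=s, end=s + 50, species=species)
             for g, c, s in placements]
    return Genome.from_genes(species, genes)


def hits_to_objects(rows):
    return [HomologyHit(r[0], r[1], r[2], r[11], r[10]) for r in rows]


@pytest.fixture(scope="session")
def sim_default():
    """One default simulation shared across the suite."""
    return run_simulation(SimParams(seed=0))


@pytest.fixture(scope="session")
def sim_hits(sim_default):
    return hits_to_objects(synthetic_homology_rows(sim_default))


@pytest.fixture(scope="session")
def sim_analysis(sim_default, sim_hits):
    """Full reference analysis (blocks + Ks + table) of the default run."""
    return reference_analysis(
        sim_default.genomes["ref"], sim_default.genomes, sim_hits, sim_default.cds)
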