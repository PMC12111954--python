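"""Core domain types: genes, genomes, homology hits and the species tree.

Coordinates are 1-based inclusive throughout (the GFF3 convention); BED input
is converted at the IO boundary.  The collinearity coordinate is the gene
*rank* — the 0-based order index of a gene along its chromosome sorted by
start — matching dot-plot practice; base pairs are retained only for the
1-Mb windowed retention statistics.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import dendropy

logger = logging.getLogger(__name__)

_ORDINAL_RE = re.compile(r"(\d+)\s*$")


def chromosome_ordinal(label: str, fallback: int | None = None) -> int:
    """Parse the chromosome ordinal number from a label.

    Strips any leading "chr"/species prefix and reads the trailing integer
    ("chr07" -> 7, "Os12" -> 12).  Non-numeric labels get the supplied
    fallback (position in file order), with a log line.
    """
    m = _ORDINAL_RE.search(label)
    if m:
        return int(m.group(1))
    if fallback is None:
        raise ValueError(f"chromosome label {label!r} has no ordinal and no fallback")
    logger.info("chromosome label %r is non-numeric; using file-order ordinal %d", label, fallback)
    return fallback


@dataclass
class Gene:
    id: str
    species: str
    chromosome: str
    chrom_ordinal: int
    start: int
    end: int
    strand: str
    rank: int = -1

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")


@dataclass
class Genome:
    """An ordered per-chromosome gene catalogue for one species."""

    species: str
    chromosomes: dict[str, list[Gene]] = field(default_factory=dict)
    genome_length: int | None = None

    @classmethod
    def from_genes(cls, species: str, genes: list[Gene], genome_length: int | None = None) -> "Genome":
        """Build a Genome, sorting genes by start and assigning ranks.

        Raises on duplicate gene ids; silently sorts unsorted input with a
        log line.
        """
        seen: set[str] = set()
        chroms: dict[str, list[Gene]] = {}
        for g in genes:
            if g.id in seen:
                raise ValueError(f"duplicate gene id {g.id!r}")
            seen.add(g.id)
            if g.species != species:
                raise ValueError(f"gene {g.id} species {g.species!r} != genome species {species!r}")
            chroms.setdefault(g.chromosome, []).append(g)
        for label, lst in chroms.items():
            if any(lst[i].start > lst[i + 1].start for i in range(len(lst) - 1)):
                logger.info("%s/%s: genes not sorted by start; sorting", species, label)
                lst.sort(key=lambda g: (g.start, g.end, g.id))
            for rank, g in enumerate(lst):
                g.rank = rank
        if genome_length is None:
            genome_length = sum(lst[-1].end for lst in chroms.values() if lst)
        return cls(species=species, chromosomes=chroms, genome_length=genome_length)

    @property
    def genes_by_id(self) -> dict[str, Gene]:
        return {g.id: g for lst in self.chromosomes.values() for g in lst}

    @property
    def n_genes(self) -> int:
        return sum(len(lst) for lst in self.chromosomes.values())

    def genes(self):
        for label in self.chromosomes:
            yield from self.chromosomes[label]


@dataclass
class HomologyHit:
    """One row of a 12-column tabular protein homology search."""

    query_gene: str
    subject_gene: str
    percent_identity: float
    bit_score: float
    e_value: float

    @property
    def is_self(self) -> bool:
        return self.query_gene == self.subject_gene


class SpeciesTree:
    """A rooted species tree with branch lengths in My.

    Thin wrapper over a dendropy tree; leaf labels are species names and must
    be unique.  Branch lengths may alternatively be in Ks units, declared via
    ``units``.
    """

    def __init__(self, tree: dendropy.Tree, units: str = "My"):
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels in species tree")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")
        self.tree = tree
        self.units = units

    @classmethod
    def from_newick(cls, newick: str, units: str = "My") -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree, units=units)

    @classmethod
    def from_file(cls, path, units: str = "My") -> "SpeciesTree":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(tree, units=units)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def root_to_leaf_depth(self, label: str) -> float:
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == label:
                return lf.distance_from_root()
        raise KeyError(label)
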