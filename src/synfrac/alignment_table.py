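"""The reference-anchored multi-genome collinearity table.

Rows are the reference genome's genes in chromosome-then-rank order; columns
are (species, homology-class) pairs with class in {ortholog, paralog_copy1,
paralog_copy2}; a cell holds the collinear partner's gene id or the ABSENT
dot.  This is the central structure from which all retention/loss statistics
derive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .collinearity import CollinearBlock
from .model import Genome

logger = logging.getLogger(__name__)

ABSENT = "."


@dataclass
class AlignmentTable:
    reference: str
    ref_genes: list[str]                       # row order = reference genome order
    columns: list[tuple[str, str]]             # (species, class)
    cells: dict[tuple[str, str], dict[str, str]]  # column -> ref gene -> partner id
    ref_genome: Genome | None = None

    def get(self, ref_gene: str, species: str, homology_class: str = "ortholog") -> str:
        return self.cells.get((species, homology_class), {}).get(ref_gene, ABSENT)

    def to_frame(self) -> pd.DataFrame:
        data = {"reference": self.ref_genes}
        for col in self.columns:
            name = f"{col[0]}.{col[1]}"
            colmap = self.cells.get(col, {})
            data[name] = [colmap.get(g, ABSENT) for g in self.ref_genes]
        return pd.DataFrame(data)


def _candidate_rank(block: CollinearBlock) -> tuple:
    # conflict resolution: higher block score, then more anchors, then id
    return (-block.chain_score, -block.n_anchors, block.block_id)


def build_table(
    reference: Genome,
    blocks_by_species: dict[str, list[CollinearBlock]],
    reference_self_blocks: list[CollinearBlock] | None = None,
) -> AlignmentTable:
    """Build the reference-anchored alignment table.

    ``blocks_by_species`` maps each non-reference species to its classified
    blocks against the reference (reference genes on the *a* side).
    ``reference_self_blocks`` are the reference's own intragenomic
    GCT-paralog blocks, used to fill the (reference, paralog) columns.

    For each reference gene, the (species, ortholog) cell is filled from the
    highest-scoring ortholog-class block anchor covering that gene; paralog
    columns are filled from gct_paralog-class blocks, copy1 being the
    partner on the lower-ordinal chromosome.  Cell conflicts resolve by
    block score, then anchor count, then block id; a target gene id is used
    at most once per column.
    """
    ref_genes = [g.id for g in reference.genes()]
    ref_gene_set = set(ref_genes)
    columns: list[tuple[str, str]] = []
    cells: dict[tuple[str, str], dict[str, str]] = {}

    def fill(colkey, assignments):
        """assignments: ref_gene -> list of (rank_tuple, chrom_ordinal, partner)."""
        colmap: dict[str, str] = {}
        used: set[str] = set()
        for g in ref_genes:
            for _, _, partner in sorted(assignments.get(g, [])):
                if partner not in used:
                    colmap[g] = partner
                    used.add(partner)
                    break
        cells[colkey] = colmap

    # reference paralog columns from its own GCT blocks
    if reference_self_blocks is not None:
        by_gene: dict[str, list] = {}
        for blk in reference_self_blocks:
            if blk.homology_class != "gct_paralog":
                continue
            r = _candidate_rank(blk)
            for a in blk.anchors:
                # self-comparison blocks are canonically ordered; index both sides
                by_gene.setdefault(a.gene_a.id, []).append((r, a.gene_b.chrom_ordinal, a.gene_b.id))
                by_gene.setdefault(a.gene_b.id, []).append((r, a.gene_a.chrom_ordinal, a.gene_a.id))
        for copy_i in (1, 2):
            colkey = (reference.species, f"paralog_copy{copy_i}")
            columns.append(colkey)
        _fill_paralog_columns(reference.species, by_gene, ref_genes, cells)

    for species in sorted(blocks_by_species):
        blocks = blocks_by_species[species]
        orth: dict[str, list] = {}
        para: dict[str, list] = {}
        for blk in blocks:
            r = _candidate_rank(blk)
            target = orth if blk.homology_class == "ortholog" else (
                para if blk.homology_class == "gct_paralog" else None)
            if target is None:
                continue
            for a in blk.anchors:
                if a.gene_a.id in ref_gene_set:
                    target.setdefault(a.gene_a.id, []).append((r, a.gene_b.chrom_ordinal, a.gene_b.id))
        colkey = (species, "ortholog")
        columns.append(colkey)
        fill(colkey, orth)
        for copy_i in (1, 2):
            columns.append((species, f"paralog_copy{copy_i}"))
        _fill_paralog_columns(species, para, ref_genes, cells)

    return AlignmentTable(
        reference=reference.species, ref_genes=ref_genes, columns=columns,
        cells=cells, ref_genome=reference,
    )


def _fill_paralog_columns(species, by_gene, ref_genes, cells):
    """Split per-gene paralog candidates into copy1/copy2 columns; copy1 is
    the partner on the lower-ordinal chromosome."""
    col1: dict[str, str] = {}
    col2: dict[str, str] = {}
    used: set[str] = set()
    for g in ref_genes:
        cands = sorted(by_gene.get(g, []))
        chosen: list[tuple[int, str]] = []
        for _, ordinal, partner in cands:
            if partner in used or any(p == partner for _, p in chosen):
                continue
            chosen.append((ordinal, partner))
            if len(chosen) == 2:
                break
        chosen.sort()
        if len(chosen) >= 1:
            col1[g] = chosen[0][1]
            used.add(chosen[0][1])
        if len(chosen) >= 2:
            col2[g] = chosen[1][1]
            used.add(chosen[1][1])
    cells[(species, "paralog_copy1")] = col1
    cells[(species, "paralog_copy2")] = col2


def presence_patterns(table: AlignmentTable, homology_class: str = "ortholog") -> dict[str, dict[str, bool]]:
    """Per-reference-gene presence/absence over the species columns of one
    class.  Pattern length equals the number of species columns of that
    class."""
    species = [sp for sp, cls in table.columns if cls == homology_class]
    out: dict[str, dict[str, bool]] = {}
    for g in table.ref_genes:
        out[g] = {sp: table.get(g, sp, homology_class) != ABSENT for sp in species}
    return out


def write_table(table: AlignmentTable, path) -> None:
    """Serialise the table as TSV, ABSENT encoded as a dot."""
    df = table.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# alignment table; reference={table.reference}; absent={ABSENT!r}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path, ref_genome: Genome | None = None) -> AlignmentTable:
    """Read a table written by :func:`write_table` (lossless round trip).
    Ragged rows are a hard error (enforced by the TSV parser)."""
    with open(path) as fh:
        header_comment = fh.readline()
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    reference = "reference"
    if "reference=" in header_comment:
        reference = header_comment.split("reference=")[1].split(";")[0].strip()
    ref_genes = list(df["reference"])
    columns = []
    cells: dict[tuple[str, str], dict[str, str]] = {}
    for name in df.columns[1:]:
        sp, cls = name.rsplit(".", 1)
        columns.append((sp, cls))
        colmap = {}
        for g, v in zip(ref_genes, df[name]):
            if v != ABSENT:
                colmap[g] = v
        cells[(sp, cls)] = colmap
    return AlignmentTable(reference=reference, ref_genes=ref_genes, columns=columns,
                          cells=cells, ref_genome=ref_genome)
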