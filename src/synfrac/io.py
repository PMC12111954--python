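"""Readers and writers for the standard formats the pipeline touches.

Gene positions come from GFF3 (features of type ``gene``) or BED (4+
columns); homology hits from 12-column BLAST tabular (outfmt 6).  All
outputs are TSV with a commented header line.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .model import Gene, Genome, HomologyHit, chromosome_ordinal

logger = logging.getLogger(__name__)

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for field in attr.strip().split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_positions(path, species: str) -> Genome:
    """Read gene positions from a GFF3 or BED file into a Genome.

    GFF3: features of type ``gene`` with an ``ID`` attribute. BED (0-based
    half-open) is converted to 1-based inclusive coordinates.  Ranks are
    assigned per chromosome by ascending start.  Duplicate gene ids are a
    hard error; unsorted input is sorted silently with a log line.
    """
    path = Path(path)
    is_gff = path.suffix.lower() in (".gff", ".gff3") or _sniff_gff(path)
    genes: list[Gene] = []
    chrom_order: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if is_gff:
                if len(f) < 9:
                    raise ValueError(f"{path}:{ln}: malformed GFF3 line")
                if f[2] != "gene":
                    continue
                attrs = _parse_gff3_attributes(f[8])
                gid = attrs.get("ID")
                if gid is None:
                    raise ValueError(f"{path}:{ln}: gene feature without ID attribute")
                chrom, start, end = f[0], int(f[3]), int(f[4])
                strand = f[6] if f[6] in "+-" else "+"
            else:
                if len(f) < 4:
                    raise ValueError(f"{path}:{ln}: BED needs >= 4 columns")
                chrom, gid = f[0], f[3]
                start, end = int(f[1]) + 1, int(f[2])
                strand = f[5] if len(f) > 5 and f[5] in "+-" else "+"
            if chrom not in chrom_order:
                chrom_order.append(chrom)
            genes.append(Gene(
                id=gid, species=species, chromosome=chrom,
                chrom_ordinal=chromosome_ordinal(chrom, fallback=chrom_order.index(chrom) + 1),
                start=start, end=end, strand=strand,
            ))
    return Genome.from_genes(species, genes)


def _sniff_gff(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("##gff-version"):
                return True
            if line.startswith("#") or not line.strip():
                continue
            return len(line.split("\t")) >= 9
    return False


def write_gff3(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes():
            fh.write(
                f"{g.chromosome}\tsynfrac\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n"
            )


def read_homology_table(path) -> list[HomologyHit]:
    """Read a 12-column BLAST tabular file; one HomologyHit per row.

    Malformed rows (wrong column count, non-numeric e-value/bitscore) are
    rejected with a warning and counted.
    """
    hits: list[HomologyHit] = []
    bad = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 12:
                bad += 1
                logger.warning("%s:%d: expected 12 columns, got %d; row rejected", path, ln, len(f))
                continue
            try:
                hits.append(HomologyHit(
                    query_gene=f[0], subject_gene=f[1],
                    percent_identity=float(f[2]), bit_score=float(f[11]),
                    e_value=float(f[10]),
                ))
            except ValueError:
                bad += 1
                logger.warning("%s:%d: non-numeric field; row rejected", path, ln)
    if bad:
        logger.warning("%s: %d malformed rows rejected", path, bad)
    return hits


def write_homology_table(rows: list[tuple], path) -> None:
    """Write 12-column BLAST-tabular-compatible rows."""
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def filter_hits(hits: list[HomologyHit], max_evalue: float = 1e-5, top_n: int = 5) -> list[HomologyHit]:
    """Filter homology hits the way the homology-search stage is screened.

    Removes self-hits and hits above ``max_evalue``, then keeps at most
    ``top_n`` best hits per query by bit score.  Idempotent.
    """
    if max_evalue <= 0:
        raise ValueError("max_evalue must be > 0")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    per_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        if h.is_self or h.e_value > max_evalue:
            continue
        per_query.setdefault(h.query_gene, []).append(h)
    out: list[HomologyHit] = []
    for q in per_query:
        ranked = sorted(per_query[q], key=lambda h: (-h.bit_score, h.e_value, h.subject_gene))
        out.extend(ranked[:top_n])
    return out


def write_tsv(df: pd.DataFrame, path, comment: str | None = None) -> None:
    """Write a DataFrame as TSV with an optional commented header line."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
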