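"""End-to-end orchestration: homology filtering -> collinear blocks -> Ks
classification -> reference-anchored table -> loss, branch and tandem
statistics.

The in-memory functions here are the library's top-level API; ``run_pipeline``
wraps them with file IO, a run manifest, and per-stage logging for shell use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment_table import AlignmentTable, build_table, presence_patterns, write_table
from .collinearity import ChainParams, CollinearBlock, block_stats, build_anchors, chain_blocks
from .io import (filter_hits, read_gene_positions, read_homology_table, write_tsv)
from .ks import block_ks, classify_block, ng86_pairs
from .loss import (BranchLossReport, branch_rates, chromosome_loss, dollo_assign,
                   ordinal_trend, split_subgenomes, tree_branch_durations)
from .model import Genome, HomologyHit, SpeciesTree
from .tandem import clusters_frame, find_tandem, tandem_stats

logger = logging.getLogger(__name__)


@dataclass
class KsThresholds:
    t_orth: float = 0.3
    t_lo: float = 0.4
    t_hi: float = 0.9


@dataclass
class PipelineConfig:
    """Everything that affects any number in any output, with defaults."""

    gff: dict[str, str] = field(default_factory=dict)       # species -> path
    cds_fasta: dict[str, str] = field(default_factory=dict)  # species -> path
    hits: str = ""
    tree: str = ""
    reference: str = "ref"
    out: str = "synfrac_out"
    seed: int = 0
    max_evalue: float = 1e-5
    top_n: int = 5
    chain: ChainParams = field(default_factory=ChainParams)
    ks: KsThresholds = field(default_factory=KsThresholds)
    tandem_max_gap: int = 5
    window_bp: int = 1_000_000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        chain = ChainParams(**raw.pop("chain", {}))
        ks = KsThresholds(**raw.pop("ks", {}))
        return cls(chain=chain, ks=ks, **raw)


def subset_hits(hits: list[HomologyHit], genome_a: Genome, genome_b: Genome) -> list[HomologyHit]:
    """Hits whose genes resolve in the given genome pair (either direction)."""
    ids_a, ids_b = set(genome_a.genes_by_id), set(genome_b.genes_by_id)
    out = []
    for h in hits:
        if (h.query_gene in ids_a and h.subject_gene in ids_b) or (
                h.query_gene in ids_b and h.subject_gene in ids_a):
            out.append(h)
    return out


def _oriented(hits: list[HomologyHit], genome_a: Genome, genome_b: Genome) -> list[HomologyHit]:
    """Orient cross-genome hits so the query is in genome_a."""
    if genome_a is genome_b:
        return hits
    ids_a = set(genome_a.genes_by_id)
    out = []
    for h in hits:
        if h.query_gene in ids_a:
            out.append(h)
        else:
            out.append(HomologyHit(h.subject_gene, h.query_gene, h.percent_identity,
                                   h.bit_score, h.e_value))
    return out


def anchor_ks(blocks: list[CollinearBlock], cds: dict[str, np.ndarray]) -> None:
    """Attach the median anchor dS to each block, in place.

    Anchor pairs are estimated with the vectorised NG86 over equal-length
    codon arrays (the common case); unequal-length pairs are skipped with a
    warning (a protein alignment would be needed to thread them)."""
    jobs: dict[int, list[tuple[CollinearBlock, int, np.ndarray, np.ndarray]]] = {}
    skipped = 0
    for blk in blocks:
        for a in blk.anchors:
            ca, cb = cds.get(a.gene_a.id), cds.get(a.gene_b.id)
            if ca is None or cb is None or len(ca) != len(cb):
                skipped += 1
                continue
            jobs.setdefault(len(ca), []).append((blk, id(a), ca, cb))
    if skipped:
        logger.warning("anchor_ks: %d anchors without comparable CDS skipped", skipped)
    per_block: dict[str, list[float]] = {blk.block_id: [] for blk in blocks}
    for n_codons, items in jobs.items():
        mat_a = np.stack([x[2] for x in items])
        mat_b = np.stack([x[3] for x in items])
        res = ng86_pairs(mat_a, mat_b)
        for (blk, _, _, _), ds in zip(items, res["dS"]):
            per_block[blk.block_id].append(float(ds))
    for blk in blocks:
        blk.ks, _ = block_ks(per_block[blk.block_id])


def classify_blocks(blocks: list[CollinearBlock], thresholds: KsThresholds) -> None:
    for blk in blocks:
        blk.homology_class = classify_block(blk.ks, thresholds.t_orth, thresholds.t_lo, thresholds.t_hi)


def pair_blocks(
    genome_a: Genome, genome_b: Genome, hits: list[HomologyHit],
    cds: dict[str, np.ndarray] | None = None,
    chain: ChainParams | None = None, thresholds: KsThresholds | None = None,
    max_evalue: float = 1e-5, top_n: int = 5,
) -> list[CollinearBlock]:
    """Filter hits, chain blocks and (when CDSs are given) classify them by
    Ks for one genome pair."""
    sub = filter_hits(_oriented(subset_hits(hits, genome_a, genome_b), genome_a, genome_b),
                      max_evalue=max_evalue, top_n=top_n)
    anchors = build_anchors(sub, genome_a, genome_b)
    blocks = chain_blocks(anchors, chain or ChainParams())
    if cds is not None:
        anchor_ks(blocks, cds)
        classify_blocks(blocks, thresholds or KsThresholds())
    return blocks


def gct_regions_from_blocks(ref_self_blocks: list[CollinearBlock]) -> list[dict]:
    """Describe the reference's GCT block pairs as subgenome regions."""
    regions = []
    for blk in ref_self_blocks:
        if blk.homology_class != "gct_paralog":
            continue
        regions.append({
            "region_id": blk.block_id,
            "genes_a": [a.gene_a.id for a in blk.anchors],
            "genes_b": [a.gene_b.id for a in blk.anchors],
            "chrom_a": blk.chrom_a, "chrom_b": blk.chrom_b,
            "ordinal_a": blk.anchors[0].gene_a.chrom_ordinal,
            "ordinal_b": blk.anchors[0].gene_b.chrom_ordinal,
        })
    return regions


@dataclass
class ReferenceAnalysis:
    table: AlignmentTable
    blocks_by_species: dict[str, list[CollinearBlock]]
    ref_self_blocks: list[CollinearBlock]
    gct_regions: list[dict]


def reference_analysis(
    reference: Genome, species_genomes: dict[str, Genome],
    hits: list[HomologyHit], cds: dict[str, np.ndarray],
    chain: ChainParams | None = None, thresholds: KsThresholds | None = None,
    max_evalue: float = 1e-5, top_n: int = 5,
) -> ReferenceAnalysis:
    """Blocks for reference-vs-each-species and reference-vs-self, then the
    reference-anchored alignment table."""
    blocks_by_species = {}
    for sp, g in sorted(species_genomes.items()):
        if sp == reference.species:
            continue
        blocks_by_species[sp] = pair_blocks(
            reference, g, hits, cds, chain, thresholds, max_evalue, top_n)
    ref_self = pair_blocks(reference, reference, hits, cds, chain, thresholds,
                           max_evalue, top_n)
    table = build_table(reference, blocks_by_species, ref_self)
    return ReferenceAnalysis(
        table=table, blocks_by_species=blocks_by_species,
        ref_self_blocks=ref_self, gct_regions=gct_regions_from_blocks(ref_self),
    )


def branch_loss_analysis(
    table: AlignmentTable, tree: SpeciesTree, reference: str,
) -> BranchLossReport:
    """Dollo-assign ortholog losses to branches and convert to genes/My."""
    patterns = presence_patterns(table, "ortholog")
    counts = dollo_assign(patterns, tree, reference_species=reference)
    durations = tree_branch_durations(tree, reference_species=reference)
    return branch_rates(counts, durations)


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based pipeline run: read inputs, execute every stage, write
    stage TSVs and a manifest.  Identical config (incl. seed) gives
    identical outputs."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__, "seed": config.seed,
        "parameters": {
            "max_evalue": config.max_evalue, "top_n": config.top_n,
            "chain": asdict(config.chain), "ks": asdict(config.ks),
            "tandem_max_gap": config.tandem_max_gap, "window_bp": config.window_bp,
            "reference": config.reference,
        },
        "stages": {},
    }
    _write_manifest(out, manifest)

    def stage(name):
        def deco(fn):
            try:
                n = fn()
            except Exception as e:
                manifest["stages"][name] = {"status": "error", "error": str(e)}
                _write_manifest(out, manifest)
                raise RuntimeError(f"stage {name!r} failed: {e}") from e
            manifest["stages"][name] = {"status": "ok", "rows": n}
            _write_manifest(out, manifest)
        return deco

    state: dict = {}

    @stage("read_inputs")
    def _():
        state["genomes"] = {sp: read_gene_positions(p, sp) for sp, p in config.gff.items()}
        state["cds"] = _read_cds(config.cds_fasta)
        state["hits"] = read_homology_table(config.hits)
        state["tree"] = SpeciesTree.from_file(config.tree) if config.tree else None
        if config.reference not in state["genomes"]:
            raise ValueError(f"reference {config.reference!r} not among inputs")
        return len(state["hits"])

    @stage("blocks_and_table")
    def _():
        ref = state["genomes"][config.reference]
        ra = reference_analysis(
            ref, state["genomes"], state["hits"], state["cds"],
            config.chain, config.ks, config.max_evalue, config.top_n)
        state["ra"] = ra
        all_blocks = ra.ref_self_blocks + [b for bs in ra.blocks_by_species.values() for b in bs]
        write_tsv(_blocks_frame(all_blocks), out / "blocks.tsv",
                  comment=f"collinear blocks; min_anchors={config.chain.min_anchors}")
        write_tsv(block_stats(all_blocks), out / "block_stats.tsv")
        write_table(ra.table, out / "alignment_table.tsv")
        return len(all_blocks)

    @stage("loss")
    def _():
        ra = state["ra"]
        rows = []
        win_rows = []
        for sp in sorted(ra.blocks_by_species):
            prof = chromosome_loss(ra.table, sp, window_bp=config.window_bp)
            trend = ordinal_trend(prof, seed=config.seed)
            df = prof.per_chromosome.assign(species=sp)
            rows.append(df)
            win_rows.append(prof.per_window.assign(species=sp))
            manifest["stages"].setdefault("ordinal_trend", {})[sp] = trend
        write_tsv(pd.concat(rows), out / "retention.tsv")
        write_tsv(pd.concat(win_rows), out / "retention_windows.tsv")
        return int(sum(len(r) for r in rows))

    @stage("subgenomes")
    def _():
        ra = state["ra"]
        frames = []
        for sp in sorted(ra.blocks_by_species):
            part = split_subgenomes(ra.table, ra.gct_regions, sp)
            frames.append(part.per_chromosome)
        df = pd.concat(frames) if frames else pd.DataFrame()
        write_tsv(df, out / "subgenome_loss.tsv")
        return len(df)

    @stage("branches")
    def _():
        if state["tree"] is None:
            manifest["stages"]["branches"] = {"status": "skipped (no tree)"}
            return 0
        report = branch_loss_analysis(state["ra"].table, state["tree"], config.reference)
        write_tsv(report.table, out / "branch_loss.tsv")
        return len(report.table)

    @stage("tandem")
    def _():
        n = 0
        summaries = []
        for sp, g in sorted(state["genomes"].items()):
            intra = [h for h in state["hits"]
                     if h.query_gene in g.genes_by_id and h.subject_gene in g.genes_by_id]
            intra = filter_hits(intra, config.max_evalue, config.top_n)
            clusters = find_tandem(g, intra, max_gap=config.tandem_max_gap)
            stats = tandem_stats(clusters, g, reported_length=(g.genome_length or 1) / 1e6)
            summaries.append({k: v for k, v in stats.items() if k != "per_chromosome"})
            write_tsv(clusters_frame(clusters), out / f"tandem_{sp}.tsv",
                      comment=f"max_gap={config.tandem_max_gap} intervening genes")
            n += len(clusters)
        write_tsv(pd.DataFrame(summaries), out / "tandem_summary.tsv",
                  comment=f"max_gap={config.tandem_max_gap}; density per Mb of annotated span")
        return n

    manifest["status"] = "complete"
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _read_cds(fasta_by_species: dict[str, str]) -> dict[str, np.ndarray]:
    from Bio import SeqIO

    from .codons import encode_cds

    cds = {}
    for _, path in fasta_by_species.items():
        for rec in SeqIO.parse(str(path), "fasta"):
            cds[rec.id] = encode_cds(str(rec.seq))
    return cds


def _blocks_frame(blocks: list[CollinearBlock]) -> pd.DataFrame:
    return pd.DataFrame([
        {"block_id": b.block_id, "species_a": b.species_a, "species_b": b.species_b,
         "chrom_a": b.chrom_a, "chrom_b": b.chrom_b, "orientation": b.orientation,
         "n_anchors": b.n_anchors, "score": round(b.chain_score, 3),
         "ks": round(b.ks, 4) if b.ks == b.ks else "NA",
         "class": b.homology_class or "NA"}
        for b in blocks
    ])
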