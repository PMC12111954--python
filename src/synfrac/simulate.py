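"""Synthetic genome-evolution generator with complete ground truth.

The generator emulates the statistical structure the analysis assumes: a
7-chromosome ancestral genome, one whole-genome duplication, nested
chromosome fusions down to 12 chromosomes, branch-specific duplicate-biased
gene loss with per-chromosome-ordinal rate differences (and an optional
subgenome bias), inversions that break collinearity, tandem duplication
bursts, and codon sequences diverged to prescribed synonymous distances.

Sequences are synthetic codon arrays drawn from five fourfold-degenerate
codon families (TCN/GTN/ACN/GCN/GGN), so every third position is exactly
synonymous and every first/second-position family switch is exactly
nonsynonymous.  Synonymous divergence is applied as exact Jukes–Cantor
transition sampling at third positions, which makes the true dS of any pair
the sum of JC times along the connecting path — an analytically defined
truth the Ks estimator can be scored against.  Real CDSs with twofold sites
and unequal codon usage are deliberately out of scope of the generator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

from .codons import FOURFOLD_CODES, codon_code, decode_cds
from .io import write_gff3, write_homology_table
from .model import Gene, Genome, SpeciesTree

DEFAULT_TREE = "(ref:35.0,((A:1.0,B:1.0):9.0,C:10.0):25.0);"

# single-base family switches that stay inside the fourfold set (and are
# always nonsynonymous): prefix -> reachable prefixes
_FAMILY_MOVES = {
    "TC": ("AC", "GC"),
    "AC": ("TC", "GC"),
    "GC": ("AC", "TC", "GT", "GG"),
    "GT": ("GC", "GG"),
    "GG": ("GC", "GT"),
}
_PREFIX_OF = {p: [codon_code(p + b) for b in "ACGT"] for p in _FAMILY_MOVES}
_CODE_PREFIX = {c: p for p, codes in _PREFIX_OF.items() for c in codes}


@dataclass
class SimParams:
    """Study conditions for one simulated genome set.

    Rates are per branch of the species tree; durations come from the tree's
    branch lengths (My).  ``per_branch_loss_rate`` is either a flat
    genes/My value or a mapping from branch label (sorted leaf set joined
    with "|", e.g. ``"A|B"``) to genes/My.
    """

    n_ancestral_chromosomes: int = 7
    genes_per_chromosome: int = 360
    codon_length: int = 300
    gene_spacing_bp: int = 10_000
    fusion_plan: tuple = (("13", "2", 0.5), ("14", "3", 0.5))
    tree_newick: str = DEFAULT_TREE
    reference: str = "ref"
    per_branch_loss_rate: dict | float = field(
        default_factory=lambda: {"ref": 50.0, "A|B|C": 35.0, "C": 35.0,
                                 "A|B": 35.0, "A": 150.0, "B": 100.0})
    per_chromosome_loss_multiplier: dict | None = None  # default 0.7->1.4 ramp
    subgenome_bias: float = 1.0     # loss-weight multiplier for subgenome-B copies
    duplicate_pref: float = 0.9     # fraction of losses drawn from two-copy families
    inversion_rate: float = 1.0     # events per branch
    inversion_max_fraction: float = 0.3
    tandem_birth_rate: float = 2.0  # events per branch
    tandem_copy_ds: float = 0.02
    ds_per_my: float = 0.0025       # synonymous JC divergence per My per lineage
    dn_ds_ratio: float = 0.2        # nonsynonymous events relative to ds
    wgd_pairwise_ds: float = 0.6    # target dS between GCT paralogs within a leaf
    noise_hits: int = 0             # spurious homology rows in the emitted table
    seed: int = 0

    def chromosome_multiplier(self, ordinal: int, n_chroms: int = 12) -> float:
        if self.per_chromosome_loss_multiplier is not None:
            return self.per_chromosome_loss_multiplier.get(ordinal, 1.0)
        if n_chroms <= 1:
            return 1.0
        return 0.7 + (ordinal - 1) * (0.7 / (n_chroms - 1))

    def branch_rate(self, branch: str) -> float:
        if isinstance(self.per_branch_loss_rate, dict):
            return float(self.per_branch_loss_rate.get(branch, 0.0))
        return float(self.per_branch_loss_rate)


@dataclass
class SimGeneRec:
    lineage: str        # unique per post-WGD copy, inherited by descent
    family: str         # ancestral gene id; shared by WGD copies and tandem copies
    subgenome: str      # 'A' (pre-WGD set) or 'B' (duplicated set)
    tandem: bool
    strand: str
    cds: np.ndarray     # int codon codes


@dataclass
class SimGenome:
    """Internal simulated genome: ordered gene records per chromosome."""

    species: str
    chromosomes: dict[str, list[SimGeneRec]]

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    def records(self):
        for label in self.chromosomes:
            yield from self.chromosomes[label]

    def copy(self, species: str | None = None) -> "SimGenome":
        return SimGenome(
            species=species or self.species,
            chromosomes={
                lbl: [replace(r, cds=r.cds.copy()) for r in recs]
                for lbl, recs in self.chromosomes.items()
            },
        )

    def gene_id(self, rec: SimGeneRec) -> str:
        return f"{self.species}_{rec.lineage}"

    def to_genome(self, spacing_bp: int = 10_000, codon_length: int = 300) -> Genome:
        """Emit a coordinate Genome: genes at regular spacing by rank."""
        genes = []
        gene_len = codon_length * 3
        for lbl, recs in self.chromosomes.items():
            ordinal = int(lbl)
            for rank, rec in enumerate(recs):
                start = rank * spacing_bp + 1
                genes.append(Gene(
                    id=self.gene_id(rec), species=self.species, chromosome=lbl,
                    chrom_ordinal=ordinal, start=start, end=start + gene_len - 1,
                    strand=rec.strand,
                ))
        return Genome.from_genes(self.species, genes)

    def cds_by_id(self) -> dict[str, np.ndarray]:
        return {self.gene_id(r): r.cds for r in self.records()}


@dataclass
class SimTruth:
    """Ground-truth record of every simulated event."""

    loss_events: list = field(default_factory=list)       # (lineage, branch, chromosome)
    inversion_events: list = field(default_factory=list)  # (branch, chromosome, start_rank, length)
    tandem_events: list = field(default_factory=list)     # (branch, parent_lineage, n_copies)
    paralog_partner: dict = field(default_factory=dict)   # lineage -> WGD partner lineage
    subgenome: dict = field(default_factory=dict)         # lineage -> 'A'/'B'
    family: dict = field(default_factory=dict)            # lineage -> ancestral gene id
    tandem_copies: set = field(default_factory=set)       # lineages born by tandem events
    branch_ds: dict = field(default_factory=dict)         # branch label -> synonymous JC time
    wgd_offset_ds: float = 0.0                            # pre-tree divergence between copy sets
    branch_durations: dict = field(default_factory=dict)  # branch label -> My

    def branch_loss_counts(self, restrict_lineages: set | None = None) -> dict[str, int]:
        out: dict[str, int] = {}
        for lineage, branch, _ in self.loss_events:
            if restrict_lineages is not None and lineage not in restrict_lineages:
                continue
            out[branch] = out.get(branch, 0) + 1
        return out


def _branch_label_of(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return "|".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


def simulate_ancestor(params: SimParams, rng: np.random.Generator | None = None) -> SimGenome:
    """Build the pre-duplication ancestral genome.

    ``n_ancestral_chromosomes`` chromosomes, each with
    ``genes_per_chromosome`` genes at regular spacing; each gene carries a
    random in-frame CDS of ``codon_length`` codons drawn from the fourfold
    families (synthetic — no start/stop codons, no internal stops by
    construction).
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    chroms: dict[str, list[SimGeneRec]] = {}
    g = 0
    for c in range(1, params.n_ancestral_chromosomes + 1):
        recs = []
        for _ in range(params.genes_per_chromosome):
            cds = rng.choice(FOURFOLD_CODES, size=params.codon_length)
            recs.append(SimGeneRec(
                lineage=f"g{g:05d}", family=f"g{g:05d}", subgenome="A",
                tandem=False, strand="+" if rng.random() < 0.5 else "-", cds=cds,
            ))
            g += 1
        chroms[str(c)] = recs
    return SimGenome(species="ancestor", chromosomes=chroms)


def apply_wgd_and_fusions(
    ancestor: SimGenome, params: SimParams, truth: SimTruth | None = None,
) -> tuple[SimGenome, SimTruth]:
    """Duplicate every chromosome, apply the fusion plan, relabel by size.

    The duplicated set (subgenome B) appears as chromosomes n+1..2n; each
    fusion nests the donor chromosome's genes into the recipient at the
    given position fraction, re-ranking genes.  Remaining chromosomes are
    relabelled 1..k by descending gene count (fused neo-chromosomes are the
    biggest, hence get the smallest ordinals).  Truth records the WGD
    paralog pairing and subgenome of every lineage.
    """
    truth = truth or SimTruth()
    n = ancestor.n_chromosomes
    chroms: dict[str, list[SimGeneRec]] = {}
    labels = list(ancestor.chromosomes)
    for i, lbl in enumerate(labels):
        a_recs, b_recs = [], []
        for rec in ancestor.chromosomes[lbl]:
            ra = replace(rec, cds=rec.cds.copy())
            rb = replace(rec, lineage=rec.lineage + "b", subgenome="B", cds=rec.cds.copy())
            truth.paralog_partner[ra.lineage] = rb.lineage
            truth.paralog_partner[rb.lineage] = ra.lineage
            truth.subgenome[ra.lineage] = "A"
            truth.subgenome[rb.lineage] = "B"
            truth.family[ra.lineage] = rec.family
            truth.family[rb.lineage] = rec.family
            a_recs.append(ra)
            b_recs.append(rb)
        chroms[lbl] = a_recs
        chroms[str(n + i + 1)] = b_recs
    for donor, recipient, frac in params.fusion_plan:
        if donor not in chroms or recipient not in chroms:
            raise ValueError(f"fusion references missing chromosome {donor!r}/{recipient!r}")
        pos = int(round(frac * len(chroms[recipient])))
        chroms[recipient] = chroms[recipient][:pos] + chroms.pop(donor) + chroms[recipient][pos:]
    order = sorted(chroms, key=lambda lbl: (-len(chroms[lbl]), int(lbl)))
    relabelled = {str(i + 1): chroms[lbl] for i, lbl in enumerate(order)}
    return SimGenome(species="root", chromosomes=relabelled), truth


def _jc_evolve_third(mat: np.ndarray, t: float, rng: np.random.Generator) -> None:
    """In-place Jukes–Cantor transition sampling at codon third positions.

    ``t`` is the expected number of substitutions per site; the stationary
    transition kernel P(same) = 1/4 + 3/4*exp(-4t/3) is sampled exactly."""
    if t <= 0 or mat.size == 0:
        return
    p_same = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
    change = rng.random(mat.shape) > p_same
    if not change.any():
        return
    offset = rng.integers(1, 4, size=int(change.sum()))
    b3 = mat[change] & 3
    mat[change] = (mat[change] & ~3) | ((b3 + offset) % 4)


_PREFIX_NAMES = sorted(_FAMILY_MOVES)
_PREFIX_ID = np.full(64, -1, dtype=np.int64)
for _p, _codes in _PREFIX_OF.items():
    for _c in _codes:
        _PREFIX_ID[_c] = _PREFIX_NAMES.index(_p)
_NEIGHBOR_COUNT = np.array([len(_FAMILY_MOVES[p]) for p in _PREFIX_NAMES])
_NEIGHBOR_BASE = np.zeros((len(_PREFIX_NAMES), 4), dtype=np.int64)
for _i, _p in enumerate(_PREFIX_NAMES):
    for _j, _q in enumerate(_FAMILY_MOVES[_p]):
        _NEIGHBOR_BASE[_i, _j] = _PREFIX_OF[_q][0] & ~3


def _nonsyn_evolve(mat: np.ndarray, t_n: float, rng: np.random.Generator) -> None:
    """In-place nonsynonymous family switches at first/second positions.

    Each codon switches its family prefix with probability 1 - exp(-t_n)
    to a uniformly chosen single-base neighbour inside the fourfold set, so
    the change is always nonsynonymous, never a stop, and the third
    position stays fourfold degenerate."""
    if t_n <= 0 or mat.size == 0:
        return
    p = 1.0 - math.exp(-t_n)
    mask = rng.random(mat.shape) < p
    if not mask.any():
        return
    hit = mat[mask]
    pid = _PREFIX_ID[hit & ~3]
    k = (rng.random(len(hit)) * _NEIGHBOR_COUNT[pid]).astype(np.int64)
    mat[mask] = _NEIGHBOR_BASE[pid, k] | (hit & 3)


def _evolve_sequences(genome: SimGenome, ds: float, dn: float, rng: np.random.Generator) -> None:
    recs = list(genome.records())
    if not recs:
        return
    mat = np.stack([r.cds for r in recs])
    _jc_evolve_third(mat, ds, rng)
    _nonsyn_evolve(mat, dn, rng)
    for k, r in enumerate(recs):
        r.cds = mat[k]


def _apply_losses(
    genome: SimGenome, expected: float, params: SimParams, branch: str,
    truth: SimTruth, rng: np.random.Generator,
) -> None:
    n_chroms = genome.n_chromosomes
    n_loss = int(rng.poisson(expected))
    if n_loss == 0:
        return
    flat: list[tuple[str, int]] = []
    base_w: list[float] = []
    fam_idx: dict[str, int] = {}
    gene_fam: list[int] = []
    for lbl, recs in genome.chromosomes.items():
        for i, r in enumerate(recs):
            flat.append((lbl, i))
            w = params.chromosome_multiplier(int(lbl), n_chroms)
            if r.subgenome == "B":
                w *= params.subgenome_bias
            base_w.append(w)
            gene_fam.append(fam_idx.setdefault(r.family, len(fam_idx)))
    if not flat:
        return
    base = np.array(base_w)
    fam = np.array(gene_fam, dtype=np.int64)
    fam_count = np.bincount(fam, minlength=len(fam_idx))
    alive = np.ones(len(flat), dtype=bool)
    lost_idx: list[int] = []
    for _ in range(min(n_loss, len(flat))):
        dup = fam_count[fam] >= 2
        w = base * np.where(dup, params.duplicate_pref, 1 - params.duplicate_pref)
        w[~alive] = 0.0
        total = w.sum()
        if total <= 0:
            break
        cum = np.cumsum(w)
        pick = int(np.searchsorted(cum, rng.random() * total))
        alive[pick] = False
        fam_count[fam[pick]] -= 1
        lost_idx.append(pick)
    for pick in lost_idx:
        lbl, i = flat[pick]
        truth.loss_events.append((genome.chromosomes[lbl][i].lineage, branch, lbl))
    keep: dict[str, list[SimGeneRec]] = {lbl: [] for lbl in genome.chromosomes}
    for k, (lbl, i) in enumerate(flat):
        if alive[k]:
            keep[lbl].append(genome.chromosomes[lbl][i])
    emptied = [lbl for lbl, recs in keep.items() if not recs]
    genome.chromosomes = keep
    if emptied:
        logger.warning("%s: chromosomes %s emptied by losses on branch %s",
                       genome.species, sorted(emptied), branch)


def _apply_inversions(
    genome: SimGenome, params: SimParams, branch: str, truth: SimTruth,
    rng: np.random.Generator,
) -> None:
    n_events = int(rng.poisson(params.inversion_rate))
    labels = [lbl for lbl in genome.chromosomes if len(genome.chromosomes[lbl]) >= 2]
    if not labels:
        return
    sizes = np.array([len(genome.chromosomes[lbl]) for lbl in labels], float)
    for _ in range(n_events):
        lbl = labels[int(np.searchsorted(np.cumsum(sizes), rng.random() * sizes.sum()))]
        recs = genome.chromosomes[lbl]
        max_len = max(2, int(params.inversion_max_fraction * len(recs)))
        length = int(rng.integers(2, max_len + 1))
        start = int(rng.integers(0, len(recs) - length + 1))
        seg = recs[start:start + length][::-1]
        for r in seg:
            r.strand = "+" if r.strand == "-" else "-"
        genome.chromosomes[lbl] = recs[:start] + seg + recs[start + length:]
        truth.inversion_events.append((branch, lbl, start, length))


def _apply_tandem(
    genome: SimGenome, params: SimParams, branch: str, truth: SimTruth,
    rng: np.random.Generator,
) -> None:
    n_events = int(rng.poisson(params.tandem_birth_rate))
    for _ in range(n_events):
        labels = [lbl for lbl in genome.chromosomes if genome.chromosomes[lbl]]
        if not labels:
            return
        sizes = np.array([len(genome.chromosomes[lbl]) for lbl in labels], float)
        lbl = labels[int(np.searchsorted(np.cumsum(sizes), rng.random() * sizes.sum()))]
        recs = genome.chromosomes[lbl]
        i = int(rng.integers(len(recs)))
        parent = recs[i]
        n_copies = int(rng.geometric(0.6))
        copies = []
        for k in range(n_copies):
            cds = parent.cds.copy()
            _jc_evolve_third(cds.reshape(1, -1), params.tandem_copy_ds, rng)
            lin = f"{parent.lineage}.t{len(truth.tandem_copies) + k}"
            copies.append(SimGeneRec(
                lineage=lin, family=parent.family, subgenome=parent.subgenome,
                tandem=True, strand=parent.strand, cds=cds,
            ))
            truth.family[lin] = parent.family
            truth.subgenome[lin] = parent.subgenome
        genome.chromosomes[lbl] = recs[:i + 1] + copies + recs[i + 1:]
        truth.tandem_copies.update(c.lineage for c in copies)
        truth.tandem_events.append((branch, parent.lineage, n_copies))


def evolve_along_tree(
    root_genome: SimGenome, params: SimParams, truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, SimGenome], SimTruth]:
    """Evolve the post-WGD root genome along the species tree.

    On each branch, in fixed order: gene losses (expected count = branch
    rate x duration, distributed by chromosome multiplier, subgenome bias
    and duplicate preference), inversions, tandem bursts, then sequence
    divergence (synonymous JC time = ds_per_my x duration).  Returns the
    leaf genomes keyed by species and the completed truth.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    tree = SpeciesTree.from_newick(params.tree_newick)
    depth = max(tree.root_to_leaf_depth(lf) for lf in tree.leaf_labels)
    truth.wgd_offset_ds = max(0.0, params.wgd_pairwise_ds - 2.0 * params.ds_per_my * depth)
    # pre-tree divergence between the two copy sets, split evenly
    recs = list(root_genome.records())
    half = truth.wgd_offset_ds / 2.0
    for sub in ("A", "B"):
        sub_recs = [r for r in recs if r.subgenome == sub]
        if sub_recs and half > 0:
            mat = np.stack([r.cds for r in sub_recs])
            _jc_evolve_third(mat, half, rng)
            for k, r in enumerate(sub_recs):
                r.cds = mat[k]

    leaves: dict[str, SimGenome] = {}

    def descend(node, genome: SimGenome):
        for child in node.child_nodes():
            label = _branch_label_of(child)
            duration = float(child.edge.length or 0.0)
            child_genome = genome.copy(species=label if child.is_leaf() else f"anc_{label}")
            truth.branch_durations[label] = duration
            _apply_losses(child_genome, params.branch_rate(label) * duration,
                          params, label, truth, rng)
            _apply_inversions(child_genome, params, label, truth, rng)
            _apply_tandem(child_genome, params, label, truth, rng)
            ds = params.ds_per_my * duration
            truth.branch_ds[label] = ds
            _evolve_sequences(child_genome, ds, ds * params.dn_ds_ratio, rng)
            if child.is_leaf():
                leaves[label] = child_genome
            else:
                descend(child, child_genome)

    descend(tree.tree.seed_node, root_genome)
    return leaves, truth


@dataclass
class SimulationResult:
    params: SimParams
    tree: SpeciesTree
    genomes: dict[str, Genome]
    cds: dict[str, np.ndarray]          # gene id -> codon codes
    truth: SimTruth
    sim_genomes: dict[str, SimGenome]

    def reference_genome(self) -> Genome:
        return self.genomes[self.params.reference]


def run_simulation(params: SimParams) -> SimulationResult:
    """Ancestor -> WGD+fusions -> tree evolution, with a single seeded
    random stream and fixed event order (deterministic for fixed params)."""
    rng = np.random.default_rng(params.seed)
    ancestor = simulate_ancestor(params, rng)
    root, truth = apply_wgd_and_fusions(ancestor, params)
    sim_leaves, truth = evolve_along_tree(root, params, truth, rng)
    genomes = {sp: g.to_genome(params.gene_spacing_bp, params.codon_length)
               for sp, g in sim_leaves.items()}
    cds: dict[str, np.ndarray] = {}
    for g in sim_leaves.values():
        cds.update(g.cds_by_id())
    return SimulationResult(
        params=params, tree=SpeciesTree.from_newick(params.tree_newick),
        genomes=genomes, cds=cds, truth=truth, sim_genomes=sim_leaves,
    )


# --- truth-aware helpers --------------------------------------------------

def true_pair_ds(result: SimulationResult, gene_a: str, gene_b: str) -> float:
    """True synonymous distance between two emitted genes: JC times summed
    along the connecting path, plus the WGD offset for cross-subgenome
    pairs and the tandem-copy offset per tandem endpoint."""
    truth, params = result.truth, result.params
    sp_a, lin_a = gene_a.split("_", 1)
    sp_b, lin_b = gene_b.split("_", 1)
    base_a = lin_a.split(".t")[0]
    base_b = lin_b.split(".t")[0]
    cross_sub = truth.subgenome.get(base_a) != truth.subgenome.get(base_b)
    if cross_sub:
        # the copies split at the WGD, before the tree root: full root-to-
        # leaf paths on both sides plus the pre-tree offset
        path = (result.tree.root_to_leaf_depth(sp_a)
                + result.tree.root_to_leaf_depth(sp_b))
        ds = truth.wgd_offset_ds + params.ds_per_my * path
    elif sp_a == sp_b:
        ds = 0.0
    else:
        pdm = getattr(result, "_pdm", None)
        if pdm is None:
            pdm = result.tree.tree.phylogenetic_distance_matrix()
            result._pdm = pdm
        taxa = {tx.label: tx for tx in result.tree.tree.taxon_namespace}
        ds = params.ds_per_my * float(pdm.distance(taxa[sp_a], taxa[sp_b]))
    ds += params.tandem_copy_ds * (lin_a != base_a) + params.tandem_copy_ds * (lin_b != base_b)
    return ds


def true_anchor_pairs(result: SimulationResult, sp_a: str, sp_b: str) -> set[frozenset]:
    """Truth collinear pairs between two genomes: ortholog pairs (same
    lineage) plus GCT-paralog pairs (WGD-partnered lineages), tandem-born
    copies excluded."""
    truth = result.truth
    lin_a = {r.lineage: result.sim_genomes[sp_a].gene_id(r)
             for r in result.sim_genomes[sp_a].records() if not r.tandem}
    lin_b = {r.lineage: result.sim_genomes[sp_b].gene_id(r)
             for r in result.sim_genomes[sp_b].records() if not r.tandem}
    pairs: set[frozenset] = set()
    for lin, ga in lin_a.items():
        if sp_a != sp_b and lin in lin_b:
            pairs.add(frozenset((ga, lin_b[lin])))
        partner = truth.paralog_partner.get(lin)
        if partner is not None and partner in lin_b:
            gb = lin_b[partner]
            if ga != gb:
                pairs.add(frozenset((ga, gb)))
    return pairs


def tandem_gene_ids(result: SimulationResult, species: str) -> set[str]:
    return {f"{species}_{lin}" for lin in result.truth.tandem_copies
            if f"{species}_{lin}" in result.cds}


def synthetic_homology_rows(result: SimulationResult, rng: np.random.Generator | None = None) -> list[tuple]:
    """BLAST-tabular-compatible rows for every within-family gene pair
    across and within the leaf genomes, plus ``params.noise_hits`` spurious
    rows.  Bit scores decay with true synonymous distance."""
    rng = rng if rng is not None else np.random.default_rng(result.params.seed + 1)
    fam_members: dict[str, list[str]] = {}
    for sp, g in result.sim_genomes.items():
        for r in g.records():
            fam_members.setdefault(r.family, []).append(g.gene_id(r))
    rows: list[tuple] = []
    n_codons = result.params.codon_length
    aln_len = n_codons * 3
    for fam in sorted(fam_members):
        members = sorted(fam_members[fam])
        for i, ga in enumerate(members):
            for gb in members[i + 1:]:
                ds = true_pair_ds(result, ga, gb)
                pident = round(100.0 * math.exp(-ds / 2.0), 1)
                bits = round(max(60.0, 2.0 * aln_len * math.exp(-ds)), 1)
                mism = int(aln_len * (1 - pident / 100))
                rows.append((ga, gb, pident, aln_len, mism, 0, 1, aln_len, 1, aln_len, 1e-50, bits))
                rows.append((gb, ga, pident, aln_len, mism, 0, 1, aln_len, 1, aln_len, 1e-50, bits))
    all_ids = sorted(result.cds)
    for _ in range(result.params.noise_hits):
        ga, gb = rng.choice(all_ids, size=2, replace=False)
        rows.append((ga, gb, 35.0, aln_len, aln_len // 2, 3, 1, aln_len, 1, aln_len, 1e-6, 62.0))
    return rows


def diverge_codon_pairs(
    n_pairs: int, n_codons: int, target_ds: float,
    seed: int | np.random.Generator = 0, dn: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate codon-array pairs at a prescribed true synonymous distance.

    Each pair descends from a random fourfold-family ancestor; each copy
    receives JC time ``target_ds``/2 at third positions (and optional
    nonsynonymous family switches at rate ``dn`` per codon).  Returns two
    (n_pairs, n_codons) codon-code arrays."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    anc = rng.choice(FOURFOLD_CODES, size=(n_pairs, n_codons))
    a, b = anc.copy(), anc.copy()
    _jc_evolve_third(a, target_ds / 2.0, rng)
    _jc_evolve_third(b, target_ds / 2.0, rng)
    if dn > 0:
        _nonsyn_evolve(a, dn / 2.0, rng)
        _nonsyn_evolve(b, dn / 2.0, rng)
    return a, b


def emit_fixture(result: SimulationResult, outdir) -> dict[str, Path]:
    """Write the simulated set as standard files: GFF3 + FASTA per species,
    a homology table, the Newick tree, and truth TSVs.  Deterministic for
    fixed params."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    for sp, genome in sorted(result.genomes.items()):
        gff = outdir / f"{sp}.gff3"
        write_gff3(genome, gff)
        manifest[f"gff:{sp}"] = gff
        fasta = outdir / f"{sp}.cds.fasta"
        with open(fasta, "w") as fh:
            for g in genome.genes():
                fh.write(f">{g.id}\n{decode_cds(result.cds[g.id])}\n")
        manifest[f"fasta:{sp}"] = fasta
    hom = outdir / "homology.tsv"
    write_homology_table(synthetic_homology_rows(result), hom)
    manifest["homology"] = hom
    treef = outdir / "tree.nwk"
    treef.write_text(result.tree.as_newick() + "\n")
    manifest["tree"] = treef
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    t = result.truth
    with open(truth_dir / "loss_events.tsv", "w") as fh:
        fh.write("lineage\tbranch\tchromosome\n")
        for lin, br, ch in t.loss_events:
            fh.write(f"{lin}\t{br}\t{ch}\n")
    with open(truth_dir / "inversions.tsv", "w") as fh:
        fh.write("branch\tchromosome\tstart_rank\tlength\n")
        for row in t.inversion_events:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(truth_dir / "tandem_events.tsv", "w") as fh:
        fh.write("branch\tparent_lineage\tn_copies\n")
        for row in t.tandem_events:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(truth_dir / "branch_ds.tsv", "w") as fh:
        fh.write("branch\tds\tduration_my\n")
        for br in sorted(t.branch_ds):
            fh.write(f"{br}\t{t.branch_ds[br]:.6f}\t{t.branch_durations.get(br, 0):.4f}\n")
    manifest["truth"] = truth_dir
    return manifest
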