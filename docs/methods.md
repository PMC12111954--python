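# Methods

`synfrac` analyses gene retention and loss in a set of genomes that share an
ancient whole-genome duplication, using one genome as the collinearity
reference. This note records the models and procedures the package
implements, the parameters that matter, and the choices made where the
design was genuinely open.

## Coordinates and domain model

Genes carry 1-based inclusive base-pair spans (BED input is converted at the
boundary) and a *rank*: the 0-based order index along their chromosome
sorted by start. Rank — not base pairs — is the collinearity coordinate, as
in standard dot-plot practice; base pairs reappear only in the 1-Mb windowed
retention profiles. Each chromosome label is parsed for its ordinal number
(`chr07` → 7); non-numeric labels fall back to file order, logged. The
ordinal matters because the headline statistic of the analysis is the trend
of gene-loss fraction against chromosome ordinal.

Homology hits are 12-column tabular protein-search rows. Before anchoring
they are screened: self-hits removed, hits above an E-value ceiling
(default 1e-5, the conventional loose threshold that still admits ancient
paralogs) removed, and at most `top_n` (default 5) hits kept per query by
bit score — a cap that bounds spurious anchors without losing the ortholog
plus the one surviving duplication partner plus nearby tandem copies. The
filtered hit set is treated as undirected: a pair reported in both
directions collapses to one anchor keeping the larger bit score.

## Collinear block chaining

Anchors (homologous gene pairs at rank coordinates, grouped by chromosome
pair) are chained by exact O(n²) dynamic programming, run separately for
the two orientations, with strict monotonicity in both rank coordinates.
The chain score is

    score = Σ anchor_score − gap_penalty·(skipped ranks)
                           − skip_penalty·(competing anchors jumped over)

A transition may span at most `max_gap` (default 25) ranks on either axis.
The third term is the load-bearing design choice: fractionation constantly
punches 1–2-rank holes in chains, so the per-rank gap penalty must be small
(default 0.05 per rank against an anchor score of 1.0), but a chain must
not bridge cheaply across an inverted segment. The two pressures cannot be
reconciled with a single per-rank penalty; charging instead for every
*anchor* whose rank lies strictly between two chained anchors (default 1.2
per anchor, computed against the full anchor set of the chromosome pair,
including anchors already claimed by other blocks) makes fractionation gaps
— which contain no anchors — cheap, and inversion bridges — which jump over
real anchors — expensive. An internal inversion therefore splits a diagonal
into its three natural blocks with orientations +/−/+.

Chains are extracted best-first; each anchor belongs to at most one block
(so Table-style collinear-gene totals never double-count); extraction stops
once the best remaining chain is shorter than `min_anchors` (default 5).
Because the extraction order does not depend on `min_anchors`, raising it
can only remove blocks. The DP is verified in the tests against exhaustive
enumeration over all anchor subsets for sets of up to 15 anchors.

Block significance is a closed approximation: for a block of m anchors
whose rank envelope covers fraction q of the chromosome-pair grid carrying
n anchors in total, the expected number of co-monotone m-subsets landing in
the envelope is E = 2·C(n,m)·qᵐ/m! (m uniform points in a box are
co-increasing with probability 1/m! per orientation), and p = min(1, E) is
the Markov bound. A Monte-Carlo oracle (`block_significance_mc`) samples
the null directly for tests. A single-rank envelope is degenerate and gets
p = 1.

## Synonymous distance (Ks) estimation

The estimator is classic pathway-counting NG86. Per codon, each position
contributes a synonymous-site fraction equal to the share of its three
single-base changes that preserve the amino acid (changes into stop codons
count as nonsynonymous), so S + N = 3·(codons) exactly; fractions are
averaged over the two sequences. Codon pairs differing at k positions are
scored by averaging the synonymous/nonsynonymous step counts over all k!
orderings of single-step pathways, excluding pathways that pass through a
stop codon (if every ordering is stop-routed, all orderings are averaged as
a documented fallback). Distances are Jukes–Cantor corrected,
dS = −(3/4)·ln(1 − (4/3)·pS), with dS undefined (saturated) at pS ≥ 3/4.
All pair-dependent quantities are precomputed into 64×64 codon tables, so
genome-scale estimation is vectorised table lookup. The implementation is
cross-checked in the tests against an independent NG86 implementation; the
two agree to machine precision away from stop-adjacent codons, where the
other implementation scores stop→stop steps as synonymous rather than
excluding the pathway.

Block-level Ks is the **median** of the defined anchor dS values — robust
to the occasional anchor that pairs a gene with a tandem copy of its true
partner. Blocks classify as `ortholog` below 0.3 (orthologs in this clade
sit well below that), `gct_paralog` inside [0.4, 0.9] (a window around the
~0.6 duplication peak wide enough to absorb rate variation), and
`unclassified` otherwise (including saturated blocks). Ks converts to time
as T = Ks/(2r); no reliable synonymous clock rate is bundled — the rate is
a required configuration parameter and any default is documented as
arbitrary. Rate correction across species rescales each species' Ks set by
the ratio of kernel-density modes of the shared-event peak, warning when a
second mode comes within 10% of the top density.

## The reference-anchored alignment table

Rows are the reference genome's genes in chromosome-then-rank order;
columns are (species, class) with class ∈ {ortholog, paralog_copy1,
paralog_copy2}; a cell holds the collinear partner's id or a dot for
ABSENT. Ortholog cells fill from ortholog-class blocks; paralog cells from
duplication-class blocks, with exactly two paralog columns per species
(the event was a tetraploidization, so each gene has at most one surviving
partner per genome; copy1 is the partner on the lower-ordinal chromosome).
When two blocks claim one cell, the higher block score wins, then the
larger anchor count, then lexicographic block id — the tie-break chain is
arbitrary but total, because deterministic output is required for testing.
A partner gene id is used at most once per column. Paralog columns are
filled from block-level evidence only; gene-level rescue of broken blocks
is deliberately not attempted.

**Loss is operational**: a reference gene with an ABSENT ortholog cell
counts as lost in that species even if a moved, non-collinear homolog
survives in the annotation. All downstream statistics inherit this
collinearity-based definition, and real-genome numbers derived from it are
upper bounds on annotation-level loss.

## Retention, subgenomes, branch assignment

Per-chromosome loss fraction = ABSENT cells / reference genes. Windowed
retention uses half-open [k·w, (k+1)·w) windows, step = width, w = 1 Mb by
default, on reference coordinates. The ordinal trend statistic — Spearman
rank correlation of loss fraction against chromosome ordinal with a seeded
permutation p (10,000 shuffles; exact enumeration for ≤ 8 chromosomes) —
is an addition of this package: it turns the qualitative claim
"higher-numbered chromosomes lose more genes" into a testable number, and
is labelled as such in output.

Duplicated reference regions (the reference's own duplication-class block
pairs) are partitioned per species into a more-retaining and a
fewer-retaining copy by comparing retained ortholog counts side by side,
ties broken toward the lower-ordinal chromosome; regions with both copies
fully lost are excluded and counted. Aggregating per chromosome and copy
class gives the two-subgenome retention profiles.

Losses are placed on species-tree branches by Dollo parsimony: presence in
the reference row asserts ancestral presence (the reference is the
outgroup), and each gene's absent leaves are explained by one loss at the
stem of every maximal all-absent subtree — provably the minimum number of
branches, verified exhaustively in the tests against brute-force search
over all edge subsets for 8-leaf trees. Branch rate = losses/duration
(genes/My); the two-branch comparator reports (r1 − r2)/r2·100 to one
decimal. Known limitation: genes lost independently in every leaf of a
clade are merged into one stem event, so internal-branch counts are biased
downward (and the deeper stem upward) by roughly the per-path loss
probability — about 7% under the simulator's default conditions, growing
with loss rate. This is inherent to parsimony on presence/absence, not an
implementation artifact.

## Tandem clusters and enrichment

Tandem clusters are connected components of intra-chromosomal homology
edges between genes with at most `max_gap` intervening genes (default 5 —
no universal definition of "tandem" exists; 5 is a common convention and
the value is echoed in every report header). Singleton components are
discarded. The density statistic divides the tandem gene count by a
*user-declared* genome length: the published per-species table this
reproduces prints length values that are not interpretable as megabases of
the actual assemblies, so the package reproduces the printed ratio
arithmetic and leaves the unit to the caller.

Family×tandem association uses the Yates-continuity-corrected chi-squared
on the 2×2 membership table. The correction is not optional decoration:
recomputing the published per-species p-values from their printed counts
matches the corrected statistic only (e.g. 135 tandem family members among
40,701 genes → p = 6.73×10⁻²²), so the corrected form is the reference
behaviour, with the uncorrected statistic exposed for comparison. Tail
probabilities come from `scipy.stats.chi2.sf`, which is exact at the
10⁻³⁰ scale and does not underflow above ~1e-300. The generic
over-representation test applies the same 2×2 machinery per category of a
user-supplied annotation (Fisher's exact available behind a flag) with
Benjamini–Hochberg adjustment. Gene-family calls follow the two-evidence
rule: the intersection of a domain-search hit list and a homology-search
hit list.

## The simulator

The generator produces the statistical structure the analysis assumes,
with complete ground truth — every loss, inversion, tandem birth and
pairwise synonymous distance is recorded.

Scenario defaults (all configurable): a 7-chromosome ancestor with 360
genes per chromosome at regular 10-kb spacing; one whole-genome
duplication; two nested fusions reducing 14 chromosomes to 12, after which
chromosomes are relabelled 1..12 by descending gene count (fused
neo-chromosomes are the largest, hence get the smallest ordinals — the
same size-based naming that underlies the ordinal trend in real
karyotypes); evolution along the ultrametric tree
`(ref:35,((A:1,B:1):9,C:10):25)` My. Per branch, in fixed order: losses,
inversions, tandem bursts, substitutions, from a single seeded random
stream, so identical parameters give byte-identical outputs.

Losses are Poisson with expectation rate×duration (defaults: 50 genes/My
on the reference branch, 35 on internal/ingroup branches, 150 and 100 on
the two youngest terminals, echoing a recent loss burst), distributed over
genes with weight = chromosome multiplier × subgenome bias × duplicate
preference. The multiplier ramps 0.7→1.4 across ordinals 1→12 (flat
configurable, for null tests); subgenome bias (default 1.0; 2.0 in the
biased-fractionation condition) multiplies weights of duplicated-set
copies; 90% of losses are drawn from families still carrying two copies,
mirroring duplicate-biased fractionation. These rates leave leaves
retaining ~65–75% of the duplicated gene set — moderate fractionation,
chosen so that parallel-loss homoplasy stays at the level the Dollo
estimator is designed for. Inversions (1/branch) reverse a random rank
interval (≤ 30% of a chromosome) and flip strands; tandem events (2/branch)
insert 1–3 near-copies beside a random gene.

Sequences are synthetic codon arrays drawn from the five codon families
whose third position is fully fourfold degenerate and whose first two
positions admit no synonymous change (TCN, GTN, ACN, GCN, GGN). Synonymous
divergence is exact Jukes–Cantor transition sampling at third positions,
so the true dS of any pair is the sum of JC times along its path: branch
dS = 0.0025/My × duration, plus a pre-tree offset calibrated so that
within-genome duplicate pairs sit at dS = 0.6 (orthologs to the reference
then land near 0.175, and cross-species duplicates near 0.775 — inside the
classification windows they are meant to exercise). Nonsynonymous change
swaps a codon's family prefix for a single-base neighbour inside the
family set (never a stop, never synonymous, third position stays fourfold),
at 0.2× the synonymous rate. This gives an analytically defined truth for
the dS-recovery tests at the cost of realism: no twofold-degenerate sites,
no codon-usage bias, no transition/transversion asymmetry, no start/stop
codons. Passing recovery tests therefore demonstrates correctness of the
pathway counting and saturation correction, not performance on real CDS
composition.

The emitted homology table contains every within-family gene pair (both
directions) with bit scores decaying in true distance, plus a configurable
number of uniform noise rows; at zero noise it is exactly the true family
relation. What the generator does not emulate: transposable elements and
intergenic sequence, translocations between chromosomes, gene conversion
between duplicates, segmental duplications other than tandem arrays, and
assembly artifacts — absences that any transfer of simulator-validated
conclusions to real genomes must keep in mind.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the full pipeline on the
default scenario (5,040 post-duplication gene copies across four genomes,
~55,000 homology rows) — 20 seeds in the recovery tests, 10 in the
acceptance script — sizes at which every recovered quantity has stabilised
(Poisson noise on seed means < 3%) while a complete run stays in tens of
seconds. Exhaustive oracles (chain enumeration, Dollo edge subsets,
permutation enumeration) run at ≤ 15 anchors, 8 leaves and 5 chromosomes
respectively, the sizes at which enumeration is exact and fast.

Degenerate inputs resolve conservatively: empty blocks are an error for
significance; zero-margin 2×2 tables give p = 1 with a warning; zero-gene
chromosomes yield NaN fractions; zero branch durations yield NaN rates;
saturated Ks values propagate as NA and never enter medians. All
stochastic code takes explicit seeds; there is no hidden global state.
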