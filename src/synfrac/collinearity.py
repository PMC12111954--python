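"""Collinear (synteny) block detection in gene-rank coordinates.

Anchors are homologous gene pairs placed at (rank_a, rank_b); blocks are
strictly monotone chains of anchors found by sparse dynamic programming, run
separately for the two orientations and extracted best-first.  Chain score =
sum of anchor scores minus a per-skipped-rank gap penalty minus a
per-skipped-anchor penalty.  The skipped-anchor term is what keeps a chain
from cheaply bridging across an inverted segment (whose anchors it would
jump over) while leaving fractionation gaps — which contain no anchors —
cheap to cross.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .model import Gene, Genome, HomologyHit

logger = logging.getLogger(__name__)


@dataclass
class AnchorPair:
    gene_a: Gene
    gene_b: Gene
    rank_a: int
    rank_b: int
    score: float


@dataclass
class ChainParams:
    min_anchors: int = 5
    max_gap: int = 25
    gap_penalty: float = 0.05     # per skipped rank
    skip_penalty: float = 1.2     # per competing anchor jumped over
    anchor_score: float = 1.0     # flat score per anchor

    def __post_init__(self):
        if self.min_anchors < 2:
            raise ValueError("min_anchors must be >= 2")
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")


@dataclass
class CollinearBlock:
    species_a: str
    species_b: str
    chrom_a: str
    chrom_b: str
    anchors: list[AnchorPair]
    orientation: str            # '+' or '-'
    chain_score: float
    block_id: str = ""
    p_value: float | None = None
    ks: float = float("nan")
    homology_class: str | None = None

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def gene_pairs(self) -> list[tuple[str, str]]:
        return [(a.gene_a.id, a.gene_b.id) for a in self.anchors]


def build_anchors(
    hits: list[HomologyHit], genome_a: Genome, genome_b: Genome
) -> dict[tuple[str, str], list[AnchorPair]]:
    """Place filtered homology hits at rank coordinates, grouped by
    chromosome pair.

    Self-comparison (``genome_a is genome_b``) is allowed; the trivial
    diagonal (a gene against itself) is excluded and the two directed rows
    of an unordered pair are collapsed keeping the max score.  Hits whose
    genes cannot be resolved in the two genomes are skipped with a warning.
    """
    idx_a = genome_a.genes_by_id
    idx_b = genome_b.genes_by_id if genome_b is not genome_a else idx_a
    self_cmp = genome_b is genome_a
    best: dict[tuple[str, str], tuple[Gene, Gene, float]] = {}
    skipped = 0
    for h in hits:
        ga = idx_a.get(h.query_gene)
        gb = idx_b.get(h.subject_gene)
        if self_cmp and (ga is None or gb is None):
            # allow either direction of lookup in self-comparison
            ga = idx_a.get(h.query_gene)
            gb = idx_a.get(h.subject_gene)
        if ga is None or gb is None:
            skipped += 1
            continue
        if self_cmp:
            if ga.id == gb.id:
                continue
            # canonical order so A->B and B->A collapse
            if (ga.chromosome, ga.rank) > (gb.chromosome, gb.rank):
                ga, gb = gb, ga
        key = (ga.id, gb.id)
        if key not in best or h.bit_score > best[key][2]:
            best[key] = (ga, gb, h.bit_score)
    if skipped:
        logger.warning("build_anchors: %d hits with unresolvable gene ids skipped", skipped)
    grouped: dict[tuple[str, str], list[AnchorPair]] = {}
    for ga, gb, score in best.values():
        grouped.setdefault((ga.chromosome, gb.chromosome), []).append(
            AnchorPair(ga, gb, ga.rank, gb.rank, score)
        )
    for lst in grouped.values():
        lst.sort(key=lambda x: (x.rank_a, x.rank_b))
    return grouped


def _best_chain(
    a: np.ndarray, b: np.ndarray, score: np.ndarray,
    full_a_sorted: np.ndarray, full_b_sorted: np.ndarray,
    params: ChainParams, sign: int,
) -> tuple[float, list[int]]:
    """Best single chain for one orientation (sign=+1 increasing b, -1
    decreasing).  Exact O(n^2) DP.  Returns (score, member indices)."""
    n = len(a)
    if n == 0:
        return -math.inf, []
    bb = b * sign
    order = np.lexsort((bb, a))
    a_o, b_o, s_o = a[order], bb[order], score[order]
    # positional indices into the static full anchor-rank arrays, for
    # counting competing anchors strictly between two chained anchors
    ra_left = np.searchsorted(full_a_sorted, a_o, side="left")
    ra_right = np.searchsorted(full_a_sorted, a_o, side="right")
    fb = full_b_sorted * sign
    fb = np.sort(fb)
    rb_left = np.searchsorted(fb, b_o, side="left")
    rb_right = np.searchsorted(fb, b_o, side="right")

    dp = s_o.copy()
    prev = np.full(n, -1, dtype=np.int64)
    for i in range(1, n):
        da = a_o[i] - a_o[:i]
        db = b_o[i] - b_o[:i]
        ok = (da > 0) & (db > 0) & (da - 1 <= params.max_gap) & (db - 1 <= params.max_gap)
        if not ok.any():
            continue
        skipped = (ra_left[i] - ra_right[:i]) + (rb_left[i] - rb_right[:i])
        cost = params.gap_penalty * (da + db - 2) + params.skip_penalty * np.maximum(skipped, 0)
        cand = np.where(ok, dp[:i] - cost, -math.inf) + s_o[i]
        j = int(np.argmax(cand))
        if cand[j] > dp[i]:
            dp[i] = cand[j]
            prev[i] = j
    end = int(np.argmax(dp))
    chain = []
    k = end
    while k != -1:
        chain.append(k)
        k = int(prev[k])
    chain.reverse()
    return float(dp[end]), [int(order[k]) for k in chain]


def chain_blocks(
    anchors_by_pair: dict[tuple[str, str], list[AnchorPair]],
    params: ChainParams | None = None,
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks, per chromosome pair.

    Chains are extracted best-first; each anchor is assigned to at most one
    block.  Extraction stops once the best remaining chain is shorter than
    ``min_anchors`` (the extraction order itself does not depend on
    ``min_anchors``, so raising it can only remove blocks).
    """
    params = params or ChainParams()
    blocks: list[CollinearBlock] = []
    for (ca, cb), anchors in sorted(anchors_by_pair.items()):
        if not anchors:
            continue
        sp_a, sp_b = anchors[0].gene_a.species, anchors[0].gene_b.species
        a = np.array([x.rank_a for x in anchors])
        b = np.array([x.rank_b for x in anchors])
        s = np.full(len(anchors), params.anchor_score)
        full_a = np.sort(a)
        full_b = np.sort(b)
        alive = np.ones(len(anchors), dtype=bool)
        serial = 0
        while alive.sum() >= 2:
            idx = np.flatnonzero(alive)
            best = None
            for sign, orient in ((1, "+"), (-1, "-")):
                sc, chain = _best_chain(a[idx], b[idx], s[idx], full_a, full_b, params, sign)
                members = [int(idx[k]) for k in chain]
                key = (sc, len(members), orient == "+")
                if best is None or key > best[0]:
                    best = (key, members, orient, sc)
            _, members, orient, sc = best
            if len(members) < params.min_anchors or sc <= 0:
                break
            chain_anchors = sorted((anchors[k] for k in members), key=lambda x: x.rank_a)
            blocks.append(CollinearBlock(
                species_a=sp_a, species_b=sp_b, chrom_a=ca, chrom_b=cb,
                anchors=chain_anchors, orientation=orient, chain_score=sc,
                block_id=f"{sp_a}.{ca}__{sp_b}.{cb}__{serial}",
            ))
            serial += 1
            alive[members] = False
    # invariant: strict monotonicity of every emitted chain
    for blk in blocks:
        ra = [x.rank_a for x in blk.anchors]
        rb = [x.rank_b for x in blk.anchors]
        assert all(x < y for x, y in zip(ra, ra[1:])), "rank_a not strictly increasing"
        if blk.orientation == "+":
            assert all(x < y for x, y in zip(rb, rb[1:])), "rank_b not increasing"
        else:
            assert all(x > y for x, y in zip(rb, rb[1:])), "rank_b not decreasing"
    return blocks


def brute_force_best_chain(
    anchors: list[AnchorPair], params: ChainParams, full_anchors: list[AnchorPair] | None = None
) -> float:
    """Exhaustive best single-chain score over all anchor subsets (both
    orientations).  Test oracle for the DP; feasible for <= ~15 anchors."""
    full = full_anchors if full_anchors is not None else anchors
    full_a = np.sort([x.rank_a for x in full])
    full_b = np.sort([x.rank_b for x in full])
    n = len(anchors)
    best = -math.inf
    order = sorted(range(n), key=lambda k: (anchors[k].rank_a, anchors[k].rank_b))
    for mask in range(1, 1 << n):
        sel = [k for k in order if mask >> k & 1]
        for sign in (1, -1):
            chain = sorted(sel, key=lambda k: (anchors[k].rank_a, sign * anchors[k].rank_b))
            sc = 0.0
            ok = True
            prev = None
            for k in chain:
                x = anchors[k]
                if prev is not None:
                    da = x.rank_a - prev.rank_a
                    db = (x.rank_b - prev.rank_b) * sign
                    if da <= 0 or db <= 0 or da - 1 > params.max_gap or db - 1 > params.max_gap:
                        ok = False
                        break
                    lo_b, hi_b = sorted((x.rank_b, prev.rank_b))
                    skipped = (
                        int(np.searchsorted(full_a, x.rank_a, "left"))
                        - int(np.searchsorted(full_a, prev.rank_a, "right"))
                        + int(np.searchsorted(full_b, hi_b, "left"))
                        - int(np.searchsorted(full_b, lo_b, "right"))
                    )
                    sc -= params.gap_penalty * (da + db - 2) + params.skip_penalty * max(skipped, 0)
                sc += params.anchor_score
                prev = x
            if ok:
                best = max(best, sc)
    return best


def block_significance(block: CollinearBlock, n_a: int, n_b: int, n_anchors_total: int) -> float:
    """Closed-form p-value approximation for a block.

    Under uniform random placement of ``n_anchors_total`` anchors on the
    n_a x n_b rank grid, the expected number of m-anchor subsets that land
    inside the block's rank envelope and are co-monotone (either
    orientation) is E = 2 * C(n, m) * q^m / m!, with q the envelope's area
    fraction (m specific points in the envelope are monotone with
    probability 1/m! per orientation).  p = min(1, E) is the Markov bound on
    observing at least one such chain.  A degenerate single-rank envelope
    gives p = 1.
    """
    if block.n_anchors == 0:
        raise ValueError("empty block")
    if n_a <= 0 or n_b <= 0 or n_anchors_total <= 0:
        raise ValueError("counts must be positive")
    m = block.n_anchors
    ra = max(x.rank_a for x in block.anchors) - min(x.rank_a for x in block.anchors) + 1
    rb = max(x.rank_b for x in block.anchors) - min(x.rank_b for x in block.anchors) + 1
    if ra <= 1 or rb <= 1:
        return 1.0
    q = (ra / n_a) * (rb / n_b)
    n = n_anchors_total
    if m > n:
        m = n
    log_e = (
        math.log(2.0)
        + gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
        + m * math.log(q)
        - gammaln(m + 1)
    )
    return float(min(1.0, math.exp(min(log_e, 0.0))))


def block_significance_mc(
    m: int, span_a: int, span_b: int, n_a: int, n_b: int, n_total: int,
    n_reps: int = 100_000, seed: int = 0,
) -> float:
    """Monte-Carlo oracle for :func:`block_significance`.

    Places ``n_total`` anchors uniformly on the rank grid and estimates the
    probability that >= ``m`` of them fall in a span_a x span_b envelope and
    contain a co-monotone chain of length >= m (either orientation).
    """
    rng = np.random.default_rng(seed)
    xs = rng.integers(0, n_a, size=(n_reps, n_total))
    ys = rng.integers(0, n_b, size=(n_reps, n_total))
    inside = (xs < span_a) & (ys < span_b)
    counts = inside.sum(axis=1)
    hits = 0
    for r in np.flatnonzero(counts >= m):
        pts = sorted(zip(xs[r][inside[r]], ys[r][inside[r]]))
        for sign in (1, -1):
            # longest strictly-monotone chain via patience-style DP
            best_len = _lis_strict([(x, sign * y) for x, y in pts])
            if best_len >= m:
                hits += 1
                break
    return hits / n_reps


def _lis_strict(points: list[tuple[int, int]]) -> int:
    pts = sorted(points)
    n = len(pts)
    best = [1] * n
    for i in range(n):
        for j in range(i):
            if pts[j][0] < pts[i][0] and pts[j][1] < pts[i][1]:
                best[i] = max(best[i], best[j] + 1)
    return max(best, default=0)


def block_stats(blocks: list[CollinearBlock]) -> pd.DataFrame:
    """Per species-pair summary: collinear gene (anchor-pair) totals, block
    counts, and genes per block to 2 decimals (NA when no blocks)."""
    rows: dict[tuple[str, str], list[int]] = {}
    for blk in blocks:
        key = (blk.species_a, blk.species_b)
        rows.setdefault(key, [0, 0])
        rows[key][0] += blk.n_anchors
        rows[key][1] += 1
    out = []
    for (sa, sb), (genes, nblocks) in sorted(rows.items()):
        out.append({
            "species_a": sa, "species_b": sb,
            "collinear_genes": genes, "blocks": nblocks,
            "genes_per_block": genes_per_block(genes, nblocks),
        })
    return pd.DataFrame(out, columns=["species_a", "species_b", "collinear_genes", "blocks", "genes_per_block"])


def genes_per_block(n_genes: int, n_blocks: int) -> float:
    """Average collinear genes per homologous block, 2 decimals (NaN for 0
    blocks)."""
    if n_blocks == 0:
        return float("nan")
    return round(n_genes / n_blocks, 2)


def anchor_f1(
    blocks: list[CollinearBlock],
    true_pairs: set[frozenset],
    ignore_genes: set[str] | None = None,
) -> dict[str, float]:
    """Anchor-level precision/recall/F1 of detected blocks against a truth
    pair set.  Anchors touching ``ignore_genes`` (e.g. tandem-born copies
    with no unique truth pairing) are excluded from both sides."""
    ignore = ignore_genes or set()
    pred = set()
    for blk in blocks:
        for ga, gb in blk.gene_pairs():
            if ga in ignore or gb in ignore:
                continue
            pred.add(frozenset((ga, gb)))
    truth = {p for p in true_pairs if not (p & ignore)}
    tp = len(pred & truth)
    precision = tp / len(pred) if pred else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    f1 = (2 * precision * recall / (precision + recall)
          if pred and truth and (precision + recall) > 0 else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "tp": tp, "n_pred": len(pred), "n_true": len(truth)}
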