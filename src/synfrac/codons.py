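"""Genetic-code lookup tables shared by the Ks estimator and the simulator.

Codons are encoded as integers 0..63 (16*b1 + 4*b2 + b3 with A=0, C=1, G=2,
T=3).  All Nei–Gojobori quantities that depend only on the codon pair are
precomputed once at import into dense 64x64 tables so that per-gene estimates
reduce to table lookups over codon index arrays.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_standard = CodonTable.unambiguous_dna_by_id[1]


def codon_str(code: int) -> str:
    """Decode an integer codon code to its three-letter string."""
    return BASES[(code >> 4) & 3] + BASES[(code >> 2) & 3] + BASES[code & 3]


def codon_code(codon: str) -> int:
    """Encode a three-letter codon to its integer code."""
    c = codon.upper().replace("U", "T")
    return (BASE_INDEX[c[0]] << 4) | (BASE_INDEX[c[1]] << 2) | (BASE_INDEX[c[2]])


AMINO = np.empty(64, dtype="U1")
IS_STOP = np.zeros(64, dtype=bool)
for _code in range(64):
    _c = codon_str(_code)
    if _c in _standard.stop_codons:
        AMINO[_code] = "*"
        IS_STOP[_code] = True
    else:
        AMINO[_code] = _standard.forward_table[_c]


def _positions(code: int):
    return ((code >> 4) & 3, (code >> 2) & 3, code & 3)


def _with_base(code: int, pos: int, base: int) -> int:
    shift = (2 - pos) * 2
    return (code & ~(3 << shift)) | (base << shift)


# --- synonymous site fractions -------------------------------------------
# s_i at each codon position = (number of synonymous single-base changes)/3;
# changes into stop codons count as nonsynonymous, so S + N = 3 per codon.

SYN_SITES = np.zeros(64)
for _code in range(64):
    if IS_STOP[_code]:
        SYN_SITES[_code] = np.nan
        continue
    s = 0.0
    bases = _positions(_code)
    for pos in range(3):
        for b in range(4):
            if b == bases[pos]:
                continue
            alt = _with_base(_code, pos, b)
            if not IS_STOP[alt] and AMINO[alt] == AMINO[_code]:
                s += 1.0 / 3.0
    SYN_SITES[_code] = s


@lru_cache(maxsize=None)
def _pathway_counts(a: int, b: int) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts for a
    codon pair, excluding mutational pathways that pass through a stop codon
    (classic NG86).  Falls back to averaging over all pathways when every
    pathway is stop-routed."""
    diff = [p for p in range(3) if _positions(a)[p] != _positions(b)[p]]
    if not diff:
        return 0.0, 0.0
    results = []
    blocked = []
    for order in itertools.permutations(diff):
        cur = a
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = _with_base(cur, pos, _positions(b)[pos])
            if IS_STOP[nxt]:
                ok = False
            if AMINO[nxt] == AMINO[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (results if ok else blocked).append((sd, nd))
    pool = results if results else blocked
    sd = sum(x[0] for x in pool) / len(pool)
    nd = sum(x[1] for x in pool) / len(pool)
    return sd, nd


SYN_DIFF = np.zeros((64, 64))
NONSYN_DIFF = np.zeros((64, 64))
for _a in range(64):
    for _b in range(64):
        if IS_STOP[_a] or IS_STOP[_b]:
            SYN_DIFF[_a, _b] = NONSYN_DIFF[_a, _b] = np.nan
        else:
            SYN_DIFF[_a, _b], NONSYN_DIFF[_a, _b] = _pathway_counts(_a, _b)


def encode_cds(seq: str) -> np.ndarray:
    """Encode an in-frame nucleotide sequence as an int codon array."""
    s = seq.upper().replace("U", "T")
    if len(s) % 3:
        raise ValueError(f"CDS length {len(s)} not divisible by 3")
    arr = np.frombuffer(s.encode(), dtype="S1")
    idx = np.empty(len(s), dtype=np.int64)
    for b, i in BASE_INDEX.items():
        idx[arr == b.encode()] = i
    return (idx[0::3] << 4) | (idx[1::3] << 2) | idx[2::3]


def decode_cds(codes: np.ndarray) -> str:
    return "".join(codon_str(int(c)) for c in codes)


# Codon families whose third position is fully fourfold degenerate and whose
# first two positions admit no synonymous single-base change: Ser(TCN),
# Val(GTN), Thr(ACN), Ala(GCN), Gly(GGN).  Used by the simulator so that
# every emitted codon contributes exactly S=1, N=2.
FOURFOLD_PREFIXES = ("TC", "GT", "AC", "GC", "GG")
FOURFOLD_CODES = np.array(
    sorted(codon_code(p + b) for p in FOURFOLD_PREFIXES for b in BASES),
    dtype=np.int64,
)
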