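"""Nei–Gojobori (NG86) synonymous/nonsynonymous distances and Ks-based
classification of collinear-block homology class.

The NG86 estimator counts, per codon, the fraction of single-base changes
that are synonymous (averaged over the two sequences), averages observed
multi-position codon differences over all orderings of single-step mutational
pathways (excluding pathways through stop codons), and applies the
Jukes–Cantor correction dS = -(3/4)·ln(1 - (4/3)·pS).  Estimates saturate
(``defined`` = False) when pS >= 3/4.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .codons import IS_STOP, NONSYN_DIFF, SYN_DIFF, SYN_SITES, encode_cds

logger = logging.getLogger(__name__)


@dataclass
class CodonAlignment:
    """A gap-free pair of aligned codon sequences (integer codon codes)."""

    codons_a: np.ndarray
    codons_b: np.ndarray
    n_dropped: int = 0

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@dataclass
class KsValue:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    defined: bool  # False iff pS >= 3/4 (dS saturated)
    dn_defined: bool = True


def make_codon_alignment(cds_a: str, cds_b: str, protein_alignment: tuple[str, str] | None = None) -> CodonAlignment:
    """Pair two in-frame CDSs codon by codon.

    Equal-length sequences are paired directly; unequal lengths require a
    protein alignment (pair of equal-length aligned strings with ``-`` gaps)
    used to thread codons.  Gap columns and columns containing a stop codon
    are dropped and counted.
    """
    a = encode_cds(cds_a) if protein_alignment is None else None
    if protein_alignment is None:
        if len(cds_a) != len(cds_b):
            raise ValueError("unequal CDS lengths require a protein alignment")
        b = encode_cds(cds_b)
        dropped = IS_STOP[a] | IS_STOP[b]
        return CodonAlignment(a[~dropped], b[~dropped], int(dropped.sum()))
    pa, pb = protein_alignment
    if len(pa) != len(pb):
        raise ValueError("aligned protein strings must have equal length")
    ca, cb = encode_cds(cds_a), encode_cds(cds_b)
    ia = ib = 0
    cols_a, cols_b = [], []
    n_dropped = 0
    for ra, rb in zip(pa, pb):
        if ra != "-" and rb != "-":
            cols_a.append(ca[ia])
            cols_b.append(cb[ib])
        else:
            n_dropped += 1
        if ra != "-":
            ia += 1
        if rb != "-":
            ib += 1
    a = np.array(cols_a, dtype=np.int64)
    b = np.array(cols_b, dtype=np.int64)
    stop = IS_STOP[a] | IS_STOP[b] if len(a) else np.zeros(0, bool)
    n_dropped += int(stop.sum())
    return CodonAlignment(a[~stop], b[~stop], n_dropped)


def _jc(p: float) -> float:
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86(aln: CodonAlignment) -> KsValue:
    """NG86 dS/dN for one codon alignment."""
    if aln.n_codons == 0:
        raise ValueError("empty codon alignment")
    a, b = aln.codons_a, aln.codons_b
    S = float((SYN_SITES[a] + SYN_SITES[b]).sum()) / 2.0
    N = 3.0 * aln.n_codons - S
    Sd = float(SYN_DIFF[a, b].sum())
    Nd = float(NONSYN_DIFF[a, b].sum())
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    s_ok, n_ok = pS < 0.75, pN < 0.75
    return KsValue(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        dS=_jc(pS) if s_ok else float("nan"),
        dN=_jc(pN) if n_ok else float("nan"),
        defined=s_ok, dn_defined=n_ok,
    )


def ng86_pairs(codons_a: np.ndarray, codons_b: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised NG86 over many equal-length pairs.

    ``codons_a``/``codons_b`` are (n_pairs, n_codons) integer codon arrays.
    Returns arrays S, N, Sd, Nd, pS, dS, defined (dS is NaN where saturated).
    """
    S = (SYN_SITES[codons_a] + SYN_SITES[codons_b]).sum(axis=1) / 2.0
    n_codons = codons_a.shape[1]
    N = 3.0 * n_codons - S
    Sd = SYN_DIFF[codons_a, codons_b].sum(axis=1)
    Nd = NONSYN_DIFF[codons_a, codons_b].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pS = np.where(S > 0, Sd / S, 0.0)
        pN = np.where(N > 0, Nd / N, 0.0)
        defined = pS < 0.75
        dS = np.where(defined, -0.75 * np.log(np.clip(1 - pS * 4 / 3, 1e-300, None)), np.nan)
        dN = np.where(pN < 0.75, -0.75 * np.log(np.clip(1 - pN * 4 / 3, 1e-300, None)), np.nan)
    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "pS": pS, "pN": pN,
            "dS": dS, "dN": dN, "defined": defined}


def block_ks(anchor_ds: list[float]) -> tuple[float, int]:
    """Block-level Ks: median of the defined anchor dS values.

    Returns (median_dS, n_undefined); median is NaN when every anchor is
    saturated.  The median (not the mean) is used for robustness to anchor
    outliers from misassigned tandem copies.
    """
    vals = [d for d in anchor_ds if d is not None and not math.isnan(d)]
    n_undef = len(anchor_ds) - len(vals)
    if not vals:
        return float("nan"), n_undef
    return float(np.median(vals)), n_undef


def classify_block(ks: float, t_orth: float = 0.3, t_lo: float = 0.4, t_hi: float = 0.9) -> str:
    """Classify a block as ortholog / GCT paralog / unclassified by its Ks.

    Ks below ``t_orth`` (orthologs typically diverge at Ks < 0.3) ->
    ``ortholog``; Ks inside [t_lo, t_hi] (the ~0.6 tetraploidization peak)
    -> ``gct_paralog``; anything else, including NaN, -> ``unclassified``.
    """
    if not (0 < t_orth < t_lo < t_hi):
        raise ValueError("thresholds must satisfy 0 < t_orth < t_lo < t_hi")
    if ks is None or math.isnan(ks):
        return "unclassified"
    if ks < t_orth:
        return "ortholog"
    if t_lo <= ks <= t_hi:
        return "gct_paralog"
    return "unclassified"


def ks_to_time(ks: float, clock_rate: float) -> float:
    """Convert a Ks distance to a divergence time in My: T = Ks/(2r).

    ``clock_rate`` is in synonymous substitutions/site/year.  No universally
    agreed grass rate exists; the value is a configuration parameter.
    """
    if clock_rate <= 0:
        raise ValueError("clock_rate must be > 0")
    if ks is None or math.isnan(ks):
        return float("nan")
    return ks / (2.0 * clock_rate) / 1e6


def _kde_mode(values: np.ndarray, grid_n: int = 512) -> tuple[float, bool]:
    """Kernel-density mode of a Ks set; returns (mode, ambiguous_flag)."""
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        raise ValueError("empty Ks set")
    if len(values) == 1 or np.ptp(values) == 0:
        return float(values[0]), False
    kde = gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), grid_n)
    dens = kde(grid)
    mode = float(grid[np.argmax(dens)])
    # flag a second local maximum within 10% of the top density
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    peaks = np.flatnonzero(interior) + 1
    peaks = peaks[np.argsort(dens[peaks])[::-1]]
    ambiguous = len(peaks) > 1 and dens[peaks[1]] >= 0.9 * dens[peaks[0]]
    return mode, ambiguous


def rate_correct(ks_sets: dict[str, np.ndarray], reference_species: str) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Scale per-species Ks distributions so their shared-event modes align.

    Each species' Ks values are multiplied by (reference mode / species
    mode), modes located by kernel-density maximum.  Returns the scaled sets
    and the scale factors.  A multimodal set (second mode within 10% of the
    top density) triggers a warning; the largest mode is used.
    """
    ref_mode, amb = _kde_mode(np.asarray(ks_sets[reference_species]))
    if amb:
        warnings.warn(f"reference {reference_species}: ambiguous Ks mode; using largest")
    scaled, factors = {}, {}
    for sp, vals in ks_sets.items():
        mode, amb = _kde_mode(np.asarray(vals))
        if amb:
            warnings.warn(f"{sp}: ambiguous Ks mode; using largest")
        f = ref_mode / mode if mode > 0 else 1.0
        factors[sp] = f
        scaled[sp] = np.asarray(vals, float) * f
    return scaled, factors
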