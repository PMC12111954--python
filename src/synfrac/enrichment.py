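"""2x2 association testing and generic over-representation analysis.

The association between tandem duplication and a gene family (e.g. NBS-LRR
disease-resistance genes) is tested with a Yates-continuity-corrected
chi-squared on the 2x2 table of (tandem x family) membership; recomputing
the published per-species p-values from the printed counts matches only the
corrected statistic, so the corrected form is the reference behaviour.  The
same machinery drives a generic over-representation test over a
user-supplied gene -> category annotation with Benjamini–Hochberg
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import chi2, fisher_exact
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable2x2:
    a: int  # in both sets
    b: int  # in first only
    c: int  # in second only
    d: int  # in neither

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    statistic: float
    df: int
    p: float
    expected_a: float
    direction: str  # over / under


def family_intersect(domain_hits: set[str], homology_hits: set[str]) -> set[str]:
    """Two-evidence family call: genes supported by both a domain search and
    a homology search are the inferred family members."""
    return set(domain_hits) & set(homology_hits)


def table_from_counts(n_genes: int, n_tandem: int, n_family: int, n_both: int) -> ContingencyTable2x2:
    """Build the 2x2 table from marginal counts (annotated genes, tandem
    genes, family genes, family-and-tandem genes)."""
    if n_both > min(n_tandem, n_family):
        raise ValueError("n_both exceeds a margin")
    if n_tandem + n_family - n_both > n_genes:
        raise ValueError("margins exceed gene universe")
    return ContingencyTable2x2(
        a=n_both, b=n_tandem - n_both, c=n_family - n_both,
        d=n_genes - n_tandem - n_family + n_both,
    )


def yates_chi2(table: ContingencyTable2x2) -> EnrichmentResult:
    """Yates-corrected chi-squared test of independence on a 2x2 table.

    statistic = N*(max(0, |ad-bc| - N/2))^2 / ((a+b)(c+d)(a+c)(b+d)); the
    upper-tail p comes from the chi-squared distribution with 1 df at full
    double precision (values at the 1e-30 scale are exact, no underflow
    above ~1e-300).  Any zero margin gives statistic 0, p = 1 with a
    warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    margins = [(a + b), (c + d), (a + c), (b + d)]
    expected_a = (a + b) * (a + c) / n
    if 0 in margins:
        logger.warning("zero margin in 2x2 table; test undefined, p=1")
        return EnrichmentResult(0.0, 1, 1.0, expected_a, "over" if a >= expected_a else "under")
    num = n * max(0.0, abs(a * d - b * c) - n / 2.0) ** 2
    stat = num / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(chi2.sf(stat, 1))
    return EnrichmentResult(
        statistic=float(stat), df=1, p=p, expected_a=expected_a,
        direction="over" if a >= expected_a else "under",
    )


def uncorrected_chi2(table: ContingencyTable2x2) -> EnrichmentResult:
    """Pearson chi-squared without continuity correction (exposed for
    comparison)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    margins = [(a + b), (c + d), (a + c), (b + d)]
    expected_a = (a + b) * (a + c) / n
    if 0 in margins:
        return EnrichmentResult(0.0, 1, 1.0, expected_a, "over" if a >= expected_a else "under")
    stat = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return EnrichmentResult(float(stat), 1, float(chi2.sf(stat, 1)), expected_a,
                            "over" if a >= expected_a else "under")


def ora(
    target_set: set[str], annotation: pd.DataFrame, universe: set[str],
    method: str = "chi2",
) -> pd.DataFrame:
    """Over-representation of categories in a target gene set.

    ``annotation`` has columns ``gene`` and ``category``; categories with no
    member in the universe are skipped with a log line.  Per category a 2x2
    test (Yates chi-squared by default, Fisher's exact behind
    ``method='fisher'``) is computed, plus the category's share of the
    target set; p-values are Benjamini–Hochberg adjusted.
    """
    target = set(target_set)
    if not target:
        raise ValueError("empty target set")
    if not target <= set(universe):
        raise ValueError("target set not contained in universe")
    rows = []
    for cat, sub in annotation.groupby("category"):
        members = set(sub["gene"]) & set(universe)
        if not members:
            logger.info("category %s absent from universe; skipped", cat)
            continue
        a = len(target & members)
        tab = ContingencyTable2x2(
            a=a, b=len(target) - a, c=len(members) - a,
            d=len(universe) - len(target) - len(members) + a,
        )
        if method == "fisher":
            odds, p = fisher_exact([[tab.a, tab.b], [tab.c, tab.d]], alternative="two-sided")
            stat, direction = float(odds), "over" if tab.a >= (tab.a + tab.b) * (tab.a + tab.c) / tab.n else "under"
        else:
            res = yates_chi2(tab)
            stat, p, direction = res.statistic, res.p, res.direction
        rows.append({
            "category": cat, "a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d,
            "target_share_pct": round(100 * a / len(target), 2),
            "statistic": stat, "p": p, "direction": direction,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
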