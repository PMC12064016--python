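"""Odds-ratio gene-set concordance enrichment with FDR control.

For each gene-set signature the expressed-gene universe is split into a 2x2
table — (in signature x non-concordant) — and the odds ratio

    OR = (a / b) / (c / d)

measures how much more likely a signature gene is to be non-concordant
between the two platforms, where a = signature genes that are
non-concordant, b = remaining non-concordant genes, c = signature genes
that are concordant, d = remaining concordant genes.  Significance is a
two-sided Fisher exact test; multiplicity is controlled by
Benjamini-Hochberg FDR over the signatures passing the inclusion criteria
(>= 10 genes in the universe covering >= 50% of the signature).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Named gene sets (symbols) with per-set descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line — name, description, members.

    Members are de-duplicated within a set (first occurrence kept);
    malformed lines (< 3 tab-separated fields) are rejected with their line
    number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {i} has {len(parts)} fields, need >= 3")
            name, desc, *members = parts
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {i}")
            sets[name] = list(dict.fromkeys(m for m in members if m))
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions, str(path))


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in gsc.sets.items():
            desc = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def filter_signatures(
    gsc: GeneSetCollection,
    universe: set[str],
    min_genes: int = 10,
    min_frac: float = 0.5,
) -> pd.DataFrame:
    """Inclusion criteria per signature: >= ``min_genes`` members in the
    universe AND those members cover >= ``min_frac`` of the signature.

    ``pct_in_universe`` is rounded half-even to an integer percent.
    """
    if not universe:
        raise ValueError("universe is empty")
    rows = []
    for name, members in gsc.sets.items():
        inter = len(set(members) & universe)
        frac = inter / len(members)
        rows.append(
            {
                "signature": name,
                "n_genes": len(members),
                "n_in_universe": inter,
                "pct_in_universe": int(np.round(100.0 * frac)),
                "included": inter >= min_genes and frac >= min_frac,
            }
        )
    return pd.DataFrame(rows).set_index("signature")


def odds_ratio_counts(
    sig_in_universe: set[str], nonconcordant: set[str], concordant: set[str]
) -> dict:
    """2x2 counts a, b, c, d and the OR for one universe-intersected signature."""
    if nonconcordant & concordant:
        raise ValueError("non-concordant and concordant sets must be disjoint")
    a = len(sig_in_universe & nonconcordant)
    c = len(sig_in_universe & concordant)
    b = len(nonconcordant) - a
    d = len(concordant) - c
    return {"a": a, "b": b, "c": c, "d": d, **_or_values(a, b, c, d)}


def _or_values(a: int, b: int, c: int, d: int) -> dict:
    # zero-cell convention: +inf when only the numerator survives, 0 when
    # only the denominator does, NaN when both collapse; a Haldane-Anscombe
    # (+0.5) OR is carried alongside for ranking
    if b * c == 0 and a * d == 0:
        odds = np.nan
    elif b * c == 0:
        odds = np.inf
    elif a * d == 0:
        odds = 0.0
    else:
        odds = (a / b) / (c / d)
    hald = ((a + 0.5) / (b + 0.5)) / ((c + 0.5) / (d + 0.5))
    recip = 1.0 / odds if np.isfinite(odds) and 0 < odds < 1 else np.nan
    return {"odds_ratio": odds, "odds_ratio_haldane": hald, "reciprocal_or": recip}


def enrichment_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table (hypergeometric null)."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def chi2_p(a: int, b: int, c: int, d: int) -> float:
    """Chi-square variant (without continuity correction), exposed as option."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum() == 0 or (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
        return 1.0
    return float(stats.chi2_contingency(table, correction=False)[1])


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResults:
    """Full per-signature enrichment table with inclusion flags and FDR."""

    table: pd.DataFrame
    n_nonconcordant: int
    n_concordant: int
    test: str

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        t = self.table
        return t[t["included"] & (t["fdr"] < fdr)].sort_values("p")

    def summary(self) -> str:
        t = self.table
        sig = self.significant()
        return (
            "Gene-set concordance enrichment\n"
            f"  universe: {self.n_nonconcordant + self.n_concordant} expressed genes "
            f"({self.n_nonconcordant} non-concordant, {self.n_concordant} concordant)\n"
            f"  signatures: {len(t)} evaluated, {int(t['included'].sum())} included, "
            f"{len(sig)} with FDR < 0.05 ({self.test} test)"
        )


class EnrichmentAnalysis:
    """Odds-ratio enrichment of gene sets for non-concordant genes.

    Parameters
    ----------
    collection :
        Gene-set collection (symbols).
    nonconcordant, concordant :
        Disjoint gene-symbol sets partitioning the expressed universe.
    symbol_map :
        Optional mapping applied to classification symbols before counting
        (harmonizes annotation releases between the expression data and the
        gene-set source).
    """

    def __init__(
        self,
        collection: GeneSetCollection,
        nonconcordant: set[str],
        concordant: set[str],
        symbol_map: dict[str, str] | None = None,
    ):
        if symbol_map:
            nonconcordant = {symbol_map.get(g, g) for g in nonconcordant}
            concordant = {symbol_map.get(g, g) for g in concordant}
        overlap = nonconcordant & concordant
        if overlap:
            raise ValueError(
                f"classification sets overlap: {sorted(overlap)[:5]}"
            )
        self.collection = collection
        self.nonconcordant = set(nonconcordant)
        self.concordant = set(concordant)
        self.universe = self.nonconcordant | self.concordant

    def fit(
        self,
        min_genes: int = 10,
        min_frac: float = 0.5,
        test: str = "fisher",
    ) -> EnrichmentResults:
        """Count, test and BH-adjust every signature.

        FDR is computed over the signatures passing the inclusion criteria;
        excluded signatures keep their raw p but carry NaN FDR.
        """
        if test not in ("fisher", "chi2"):
            raise ValueError(f"unknown test {test!r}")
        pfun = enrichment_p if test == "fisher" else chi2_p
        cover = filter_signatures(self.collection, self.universe, min_genes, min_frac)
        rows = []
        for name, members in self.collection.sets.items():
            sig_u = set(members) & self.universe
            counts = odds_ratio_counts(sig_u, self.nonconcordant, self.concordant)
            counts["p"] = pfun(counts["a"], counts["b"], counts["c"], counts["d"])
            rows.append({"signature": name, **counts})
        table = cover.join(pd.DataFrame(rows).set_index("signature"))
        table["fdr"] = np.nan
        inc = table["included"]
        if inc.any():
            table.loc[inc, "fdr"] = bh_fdr(table.loc[inc, "p"].to_numpy())
        return EnrichmentResults(
            table, len(self.nonconcordant), len(self.concordant), test
        )
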