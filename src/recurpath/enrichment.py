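"""Over-representation analysis of DE genes against pathway and GO-term sets.

The test is the hypergeometric upper tail: with a universe of N genes (all
panel genes surviving the background filter), a term covering K of them and
n DE genes, the p-value for observing k overlapping genes is
P(X >= k), X ~ Hypergeom(N, K, n). Multiplicity is adjusted with
Benjamini–Hochberg within each category (pathways and GO biological
processes are tested against separate libraries).

Two selection tiers mirror the downstream uses: a *report* tier
(adjusted p < 0.001, top 10 per category) and a *curation* tier feeding the
pathway-centric classifiers (adjusted p < 0.05 with at least 5 DE genes for
pathways, at least 10 for GO terms). The bridge-gene analysis builds the
gene-term bipartite graph over the top-5 terms of each category and reports
genes linked to at least ``min_links`` of those terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection
from .diffexpr import bh_qvalues

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


@dataclass
class TermSelection:
    """Terms curated for classifier training, with their DE-gene feature lists."""

    term_id: str
    term_name: str
    category: str
    genes: tuple[str, ...]  # DE genes in the term


@dataclass
class BridgeGeneReport:
    terms: list[str]  # the <= 10 selected terms
    links: pd.DataFrame  # columns gene, term_id
    bridge_genes: pd.DataFrame  # columns gene, n_links; sorted by count desc then id


def hypergeom_enrich(
    de_genes: list[str],
    universe: list[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``de_genes`` in each term.

    Term gene lists are intersected with the universe before testing; terms
    with no universe overlap are skipped with a log record. Adjusted p-values
    are BH within each category.
    """
    uni = set(universe)
    de = [g for g in dict.fromkeys(de_genes)]
    outside = [g for g in de if g not in uni]
    if outside:
        raise EnrichmentError(f"DE genes outside the universe: {outside[:5]}")
    N, n = len(uni), len(de)
    de_set = set(de)
    rows = []
    for entry in collection:
        term_genes = [g for g in entry.genes if g in uni]
        K = len(term_genes)
        if K == 0:
            logger.info("hypergeom_enrich: term %s has no universe overlap; skipped", entry.term_id)
            continue
        overlap = sorted(g for g in term_genes if g in de_set)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": entry.term_id,
                "term_name": entry.term_name,
                "category": entry.category,
                "k": k,
                "K": K,
                "N": N,
                "n": n,
                "p_value": min(p, 1.0),
                "overlap_genes": ",".join(overlap),
            }
        )
    result = pd.DataFrame(rows)
    if len(result) == 0:
        return result
    result["adj_p"] = np.nan
    for cat, idx in result.groupby("category").groups.items():
        result.loc[idx, "adj_p"] = bh_qvalues(result.loc[idx, "p_value"].to_numpy())
    return result


def report_terms(
    result: pd.DataFrame,
    category: str | None = None,
    adj_cutoff: float = 0.001,
    top_n: int = 10,
) -> pd.DataFrame:
    """Report tier: terms with adj_p < cutoff, ranked ascending by adj_p
    (ties by raw p then term id), truncated to ``top_n``."""
    if len(result) == 0:
        return result
    sub = result if category is None else result[result["category"] == category]
    sub = sub[sub["adj_p"] < adj_cutoff]
    sub = sub.sort_values(["adj_p", "p_value", "term_id"], kind="mergesort")
    return sub.head(top_n).reset_index(drop=True)


def curate_for_dl(
    result: pd.DataFrame,
    adj_cutoff: float = 0.05,
    min_genes_pathway: int = 5,
    min_genes_go: int = 10,
) -> list[TermSelection]:
    """Curation tier for the classifiers: adj_p < cutoff and a per-category
    floor on the number of overlapping DE genes (5 for pathways, 10 for GO)."""
    selections: list[TermSelection] = []
    if len(result) == 0:
        return selections
    for _, row in result.sort_values(["category", "adj_p", "term_id"], kind="mergesort").iterrows():
        floor = min_genes_pathway if row["category"] == "pathway" else min_genes_go
        if row["adj_p"] < adj_cutoff and row["k"] >= floor:
            genes = tuple(row["overlap_genes"].split(",")) if row["overlap_genes"] else ()
            selections.append(
                TermSelection(row["term_id"], row["term_name"], row["category"], genes)
            )
    return selections


def bridge_genes(
    result: pd.DataFrame,
    min_links: int = 5,
    top_per_category: int = 5,
) -> BridgeGeneReport:
    """Genes linked to >= ``min_links`` of the top-5 pathways plus top-5 GO terms.

    "Top" terms are ranked by adjusted p within each category; if fewer than
    ``top_per_category`` terms exist in a category, all are used (logged).
    """
    selected_terms: list[pd.Series] = []
    for cat in ("pathway", "go_bp"):
        sub = result[result["category"] == cat].sort_values(
            ["adj_p", "p_value", "term_id"], kind="mergesort"
        )
        if len(sub) < top_per_category:
            logger.info("bridge_genes: only %d %s terms available", len(sub), cat)
        selected_terms.extend(row for _, row in sub.head(top_per_category).iterrows())
    link_rows = []
    for row in selected_terms:
        for g in (row["overlap_genes"].split(",") if row["overlap_genes"] else []):
            link_rows.append({"gene": g, "term_id": row["term_id"]})
    links = pd.DataFrame(link_rows, columns=["gene", "term_id"])
    if len(links):
        counts = links.groupby("gene").size().rename("n_links").reset_index()
        counts = counts[counts["n_links"] >= min_links]
        counts = counts.sort_values(["n_links", "gene"], ascending=[False, True], kind="mergesort")
    else:
        counts = pd.DataFrame(columns=["gene", "n_links"])
    return BridgeGeneReport(
        terms=[row["term_id"] for row in selected_terms],
        links=links,
        bridge_genes=counts.reset_index(drop=True),
    )


def write_enrichment(result: pd.DataFrame, path: str) -> None:
    cols = ["term_id", "term_name", "category", "k", "K", "N", "n", "p_value", "adj_p", "overlap_genes"]
    result[cols].to_csv(path, sep="\t", index=False)
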