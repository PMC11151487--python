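"""Consensus feature selection across bootstraps and the gene discriminant score.

A bootstrap model is *high-performing* when its test accuracy strictly
exceeds the accuracy cutoff (0.80 by default). Within a term, a gene passes
the consensus rule when its aggregated Shapley importance is >= the
importance cutoff (0.01) in at least ceil(fraction * H) of the H
high-performing models — with H = 8 and fraction 0.5 that is 4 of 8. A term
with no high performer selects nothing.

The *gene discriminant score* counts, over all curated pathways and GO
terms, how many terms selected the gene; the top 20 genes by this score form
the recurrence signature. For survival stratification, a sample is "altered"
when any signature gene's cohort z-score exceeds the z cutoff (strictly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .pairs import BootstrapResult

logger = logging.getLogger(__name__)


@dataclass
class ConsensusSelection:
    term_id: str
    category: str
    high_performers: int  # H
    required: int  # ceil(frac * H)
    table: pd.DataFrame  # gene, pass_count, mean_importance, selected


def consensus_select(
    results: list[BootstrapResult],
    category: str = "pathway",
    accuracy_cutoff: float = 0.80,
    shap_cutoff: float = 0.01,
    fraction: float = 0.50,
) -> ConsensusSelection:
    """Apply the high-performer + importance-threshold consensus rule to the
    bootstraps of one term."""
    if not results:
        raise ValueError("no bootstrap results")
    term_id = results[0].term_id
    high = [
        r for r in results
        if r.metrics["accuracy"] is not None and r.metrics["accuracy"] > accuracy_cutoff
    ]
    H = len(high)
    required = ceil(fraction * H) if H else 0
    genes = list(high[0].importance.index) if H else []
    rows = []
    for g in genes:
        imps = np.array([r.importance[g] for r in high])
        pass_count = int((imps >= shap_cutoff).sum())
        rows.append(
            {
                "gene": g,
                "pass_count": pass_count,
                "mean_importance": float(imps.mean()),
                "selected": H >= 1 and pass_count >= required,
            }
        )
    table = pd.DataFrame(rows, columns=["gene", "pass_count", "mean_importance", "selected"])
    if H == 0:
        logger.info("consensus_select: term %s has no high-performing bootstrap", term_id)
    return ConsensusSelection(term_id, category, H, required, table)


def discriminant_scores(
    selections: list[ConsensusSelection],
    top_n: int = 20,
) -> pd.DataFrame:
    """Rank genes by the number of terms that selected them.

    Ties break by mean importance across selecting models (descending), then
    gene id. Returns the full table with a ``rank`` column; the signature is
    the first ``top_n`` rows.
    """
    if not selections:
        raise ValueError("no consensus selections")
    records: dict[str, dict] = {}
    for sel in selections:
        chosen = sel.table[sel.table["selected"]]
        for _, row in chosen.iterrows():
            rec = records.setdefault(
                row["gene"],
                {"gene": row["gene"], "pathway_count": 0, "go_count": 0, "importances": []},
            )
            key = "pathway_count" if sel.category == "pathway" else "go_count"
            rec[key] += 1
            rec["importances"].append(row["mean_importance"])
    rows = []
    for rec in records.values():
        rows.append(
            {
                "gene": rec["gene"],
                "score": rec["pathway_count"] + rec["go_count"],
                "pathway_count": rec["pathway_count"],
                "go_count": rec["go_count"],
                "mean_importance": float(np.mean(rec["importances"])),
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene", "score", "pathway_count", "go_count", "mean_importance"]
    )
    if len(table):
        table = table.sort_values(
            ["score", "mean_importance", "gene"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
        table["rank"] = range(1, len(table) + 1)
    else:
        table["rank"] = []
    return table.head(top_n) if top_n else table


def altered_grouping(
    expression: pd.DataFrame,
    signature_genes: list[str],
    z_cutoff: float = 2.0,
) -> pd.Series:
    """Label each sample 'altered' if any signature gene has z > z_cutoff.

    z-scores are computed per gene across the cohort (sample SD); missing
    signature genes are logged and skipped.
    """
    present = [g for g in signature_genes if g in expression.index]
    missing = set(signature_genes) - set(present)
    if missing:
        logger.info("altered_grouping: %d signature genes absent, skipped", len(missing))
    if not present:
        raise ValueError("no signature genes present in the expression matrix")
    sub = expression.loc[present]
    arr = sub.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = np.inf  # constant genes can never mark a sample altered
    z = (arr - mean) / sd
    altered = (z > z_cutoff).any(axis=0)
    return pd.Series(np.where(altered, "altered", "unaltered"), index=sub.columns)
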