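"""Paired differential expression between recurrent and primary tumors.

The design is a strict paired contrast: each patient contributes one primary
and one recurrent sample, and per-gene log2 fold changes are means of the
per-patient log2 differences (recurrent minus primary). Significance comes
from a two-sided paired t-test on the log2 differences; false discovery is
controlled with Benjamini–Hochberg q-values (a Storey estimate with
lambda = 0.5 is available behind ``method='storey'``). A gene is called
differentially expressed when q <= q_cutoff and |linear fold change| >=
fc_cutoff, both bounds inclusive.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

Pairing = dict[str, tuple[str, str]]  # patient -> (primary sample, recurrent sample)


class DiffExprError(ValueError):
    pass


def _paired_diffs(matrix: ExpressionMatrix, pairing: Pairing) -> pd.DataFrame:
    """Per-gene, per-patient log2 differences (recurrent - primary)."""
    if matrix.scale_tag != "log2":
        matrix = matrix.to_log2()
    diffs = {}
    for patient, (primary, recurrent) in pairing.items():
        for s in (primary, recurrent):
            if s not in matrix.values.columns:
                raise DiffExprError(f"sample {s!r} (patient {patient!r}) absent from matrix")
        diffs[patient] = matrix.values[recurrent] - matrix.values[primary]
    return pd.DataFrame(diffs)


def paired_log2fc(matrix: ExpressionMatrix, pairing: Pairing) -> pd.Series:
    """Mean over patients of per-patient log2 (recurrent / primary)."""
    if not pairing:
        raise DiffExprError("empty pairing")
    return _paired_diffs(matrix, pairing).mean(axis=1)


def paired_test(matrix: ExpressionMatrix, pairing: Pairing) -> pd.Series:
    """Two-sided paired t-test p-value per gene on log2 differences.

    Degenerate genes: all differences exactly zero -> p = 1; identical
    non-zero differences (zero variance, non-zero mean) -> the t statistic
    diverges and the smallest positive float is returned, with a log record.
    """
    diffs = _paired_diffs(matrix, pairing)
    n = diffs.shape[1]
    if n < 2:
        raise DiffExprError("paired t-test needs >= 2 patients")
    arr = diffs.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise DiffExprError("non-finite paired difference")
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    p = np.ones(arr.shape[0])
    ok = sd > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    degenerate = (~ok) & (mean != 0)
    if degenerate.any():
        logger.info("paired_test: %d genes with identical non-zero differences", degenerate.sum())
        p[degenerate] = np.finfo(float).tiny
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.Series(p, index=diffs.index)


def bh_qvalues(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise DiffExprError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def storey_qvalues(p, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a single lambda: pi0 = #{p > lam} / (m (1 - lam)),
    capped at 1, times the BH q-values."""
    p = np.asarray(p, dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise DiffExprError("p-values must lie in (0, 1]")
    pi0 = min(1.0, (p > lam).sum() / (p.size * (1.0 - lam)))
    if pi0 == 0.0:
        pi0 = 1.0 / p.size  # all p tiny; keep q-values positive
    return np.minimum(bh_qvalues(p) * pi0, 1.0)


def deg_table(
    matrix: ExpressionMatrix,
    pairing: Pairing,
    q_cutoff: float = 0.05,
    fc_cutoff: float = 1.5,
    q_method: str = "bh",
) -> pd.DataFrame:
    """Full differential-expression table: log2_fc, p, q, direction."""
    log2fc = paired_log2fc(matrix, pairing)
    p = paired_test(matrix, pairing)
    q = storey_qvalues(p.to_numpy()) if q_method == "storey" else bh_qvalues(p.to_numpy())
    table = pd.DataFrame({"log2_fc": log2fc, "p_value": p, "q_value": q})
    lfc_cut = np.log2(fc_cutoff)
    passing = (table["q_value"] <= q_cutoff) & (table["log2_fc"].abs() >= lfc_cut)
    direction = np.where(~passing, "none", np.where(table["log2_fc"] > 0, "up", "down"))
    table["direction"] = direction
    return table


def select_degs(
    table: pd.DataFrame, q_cutoff: float = 0.05, fc_cutoff: float = 1.5
) -> tuple[list[str], list[str]]:
    """(upregulated, downregulated) gene lists at q <= q_cutoff and
    |linear fold change| >= fc_cutoff (inclusive bounds)."""
    if fc_cutoff <= 1:
        raise DiffExprError("fc_cutoff must exceed 1")
    lfc_cut = np.log2(fc_cutoff)
    passing = (table["q_value"] <= q_cutoff) & (table["log2_fc"].abs() >= lfc_cut)
    up = table.index[passing & (table["log2_fc"] > 0)].tolist()
    down = table.index[passing & (table["log2_fc"] < 0)].tolist()
    return up, down


def write_deg_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index_label="gene")
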