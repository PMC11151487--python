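"""Immune-cell deconvolution by constrained regression.

Bulk expression is modelled as a non-negative mixture of reference cell-type
profiles: for each sample x and signature matrix S (genes x cell types),
fractions solve min_{w >= 0} ||S w - x||_2 on the shared signature genes,
then are renormalized to sum to one. An optional per-gene median-matching
step rescales the signature to the mixture's dynamic range as a lightweight
cross-platform alignment.

Paired group comparison uses the two-sided Wilcoxon signed-rank test on
per-patient fraction differences per cell type (exact null for n <= 25),
with the conventional significance stars (* p<=0.05, ** p<=0.01,
*** p<=0.001).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

Pairing = dict[str, tuple[str, str]]


class DeconvolutionError(ValueError):
    pass


def read_signature(path: str) -> pd.DataFrame:
    """Signature TSV: first column gene, remaining columns cell types."""
    sig = pd.read_csv(path, sep="\t", index_col=0)
    if (sig.to_numpy() < 0).any():
        raise DeconvolutionError("signature matrix contains negative values")
    if (sig.sum(axis=1) == 0).any():
        raise DeconvolutionError("signature matrix contains an all-zero gene row")
    return sig


def median_match(signature: pd.DataFrame, mixture: pd.DataFrame) -> pd.DataFrame:
    """Rescale each signature gene row so its row median matches the gene's
    median expression across mixture samples (alignment analogue for
    cross-platform batch effects)."""
    shared = signature.index.intersection(mixture.index)
    sig = signature.loc[shared].copy()
    sig_med = sig.median(axis=1).replace(0, np.nan)
    mix_med = mixture.loc[shared].median(axis=1)
    scale = (mix_med / sig_med).fillna(1.0)
    return sig.mul(scale, axis=0)


def deconvolve_sample(x: pd.Series, signature: pd.DataFrame) -> tuple[pd.Series, float]:
    """Non-negative least squares fractions for one sample.

    Returns (fractions summing to 1, residual norm of the NNLS fit).
    """
    shared = signature.index.intersection(x.index)
    if len(shared) < signature.shape[1]:
        raise DeconvolutionError(
            f"only {len(shared)} shared genes for {signature.shape[1]} cell types"
        )
    S = signature.loc[shared].to_numpy(dtype=float)
    b = x.loc[shared].to_numpy(dtype=float)
    w, residual = optimize.nnls(S, b)
    total = w.sum()
    if total == 0:
        logger.info("deconvolve_sample: all-zero weights; returning uniform fractions")
        fractions = np.full(len(w), 1.0 / len(w))
    else:
        fractions = w / total
    return pd.Series(fractions, index=signature.columns), float(residual)


def deconvolve(
    matrix: ExpressionMatrix,
    signature: pd.DataFrame,
    batch_align: bool = False,
) -> pd.DataFrame:
    """Fraction table: one row per sample, one column per cell type, plus
    the per-sample residual norm."""
    sig = median_match(signature, matrix.values) if batch_align else signature
    rows, residuals = [], []
    for s in matrix.sample_ids:
        frac, res = deconvolve_sample(matrix.values[s], sig)
        rows.append(frac)
        residuals.append(res)
    table = pd.DataFrame(rows, index=matrix.sample_ids)
    table["residual"] = residuals
    return table


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def compare_fractions(fractions: pd.DataFrame, pairing: Pairing) -> pd.DataFrame:
    """Per-cell-type paired comparison between primary and recurrent samples.

    Two-sided Wilcoxon signed-rank on per-patient differences (recurrent
    minus primary), exact null for n <= 25; all-zero differences give p = 1.
    """
    cell_types = [c for c in fractions.columns if c != "residual"]
    rows = []
    n = len(pairing)
    for ct in cell_types:
        prim = np.array([fractions.loc[p, ct] for p, _ in pairing.values()])
        rec = np.array([fractions.loc[r, ct] for _, r in pairing.values()])
        diffs = rec - prim
        if np.all(diffs == 0):
            logger.info("compare_fractions: %s has all-zero differences", ct)
            p_val = 1.0
        else:
            method = "exact" if n <= 25 else "auto"
            # zero differences are dropped (wilcox handling), consistent with the exact null
            p_val = float(stats.wilcoxon(rec, prim, zero_method="wilcox", method=method).pvalue)
        rows.append(
            {
                "cell_type": ct,
                "median_primary": float(np.median(prim)),
                "median_recurrent": float(np.median(rec)),
                "median_difference": float(np.median(diffs)),
                "p_value": p_val,
                "stars": _stars(p_val),
            }
        )
    return pd.DataFrame(rows)
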