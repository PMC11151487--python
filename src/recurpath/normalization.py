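"""Count-panel normalization: background threshold from negative controls,
technical scaling from positive controls, geNorm reference-gene selection and
housekeeping normalization.

The digital count platform ships every cartridge with spike-in controls: six
positive controls on a concentration ladder and eight negative controls that
measure non-specific background. Normalization proceeds in the conventional
order: (1) positive-control scaling equalizes per-sample assay efficiency,
(2) the background threshold (mean of all negative-control counts plus two
sample standard deviations) flags genes never detected above background,
(3) housekeeping normalization scales each sample so the geometric mean of
reference genes is constant. Reference genes are chosen from the panel's
housekeeping candidates by the geNorm stability statistic M — the mean,
over partner genes, of the standard deviation of the pairwise log2 ratio —
with iterative exclusion of the least stable candidate.

Counts are offset by +1 before any log transform in control and housekeeping
computations (FFPE panels contain zeros; the offset is recorded in the log).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

LOG_OFFSET = 1.0


class NormalizationError(ValueError):
    pass


@dataclass
class ControlSet:
    """Spike-in control counts and housekeeping candidates for one run.

    ``positive_controls`` and ``negative_controls`` are control x sample count
    tables (six and eight rows on the standard panel); ``housekeeping_genes``
    names candidate reference genes present in the expression matrix.
    """

    positive_controls: pd.DataFrame
    negative_controls: pd.DataFrame
    housekeeping_genes: list[str]

    def __post_init__(self) -> None:
        for name, df in (("positive", self.positive_controls), ("negative", self.negative_controls)):
            if (df.to_numpy() < 0).any():
                raise NormalizationError(f"negative count among {name} controls")
        if self.negative_controls.size < 2:
            raise NormalizationError("need >= 2 negative-control observations")
        if len(self.housekeeping_genes) < 2:
            raise NormalizationError("need >= 2 housekeeping candidates")


@dataclass
class GeNormResult:
    """geNorm output: stability M per candidate (lower = more stable),
    candidates ranked most-to-least stable, and the selected references."""

    stability_m: dict[str, float]
    ranked_genes: list[str]
    selected_references: list[str]


def read_controls(path: str) -> ControlSet:
    """Control table TSV: columns ``control_class`` (positive/negative/housekeeping),
    ``control_id``, then one column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"control_class": str, "control_id": str})
    required = {"control_class", "control_id"}
    if not required <= set(df.columns):
        raise NormalizationError(f"control table needs columns {sorted(required)}")
    samples = [c for c in df.columns if c not in required]
    by_class = {
        cls: grp.set_index("control_id")[samples].astype(float)
        for cls, grp in df.groupby("control_class")
    }
    hk = list(by_class.get("housekeeping", pd.DataFrame()).index)
    return ControlSet(
        positive_controls=by_class.get("positive", pd.DataFrame()),
        negative_controls=by_class.get("negative", pd.DataFrame()),
        housekeeping_genes=hk,
    )


def write_controls(controls: ControlSet, path: str) -> None:
    frames = []
    for cls, df in (
        ("positive", controls.positive_controls),
        ("negative", controls.negative_controls),
    ):
        f = df.copy()
        f.insert(0, "control_id", f.index)
        f.insert(0, "control_class", cls)
        frames.append(f)
    hk = pd.DataFrame({"control_class": "housekeeping", "control_id": controls.housekeeping_genes})
    for c in controls.negative_controls.columns:
        hk[c] = np.nan
    frames.append(hk)
    pd.concat(frames).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def background_threshold(controls: ControlSet) -> float:
    """Mean + 2 sample standard deviations of all pooled negative-control counts."""
    pooled = controls.negative_controls.to_numpy(dtype=float).ravel()
    if pooled.size < 2:
        raise NormalizationError("need >= 2 negative-control observations for a standard deviation")
    return float(pooled.mean() + 2.0 * pooled.std(ddof=1))


def background_filter(matrix: ExpressionMatrix, threshold: float) -> list[str]:
    """Genes retained: above (>=) threshold in at least one sample.

    A gene is excluded only when its count falls below threshold in *every*
    sample.
    """
    keep = (matrix.values >= threshold).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("background_filter: excluded %d genes below %.3f in all samples", dropped, threshold)
    return list(matrix.values.index[keep])


# ---------------------------------------------------------------------------
# positive-control scaling
# ---------------------------------------------------------------------------

def _geomean(arr: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.exp(np.mean(np.log(arr), axis=axis))


def positive_factor(controls: ControlSet) -> pd.Series:
    """Per-sample technical scale factor from the positive-control ladder.

    factor_s = (mean over samples of the positive-control geometric mean)
               / (geometric mean of positives in sample s).
    """
    pos = controls.positive_controls.to_numpy(dtype=float)
    if (pos <= 0).any():
        raise NormalizationError("positive-control count of zero: geometric mean undefined")
    geomeans = _geomean(pos, axis=0)
    factors = geomeans.mean() / geomeans
    return pd.Series(factors, index=controls.positive_controls.columns)


def apply_factors(matrix: ExpressionMatrix, factors: pd.Series) -> ExpressionMatrix:
    missing = set(matrix.sample_ids) - set(factors.index)
    if missing:
        raise NormalizationError(f"no scale factor for samples {sorted(missing)}")
    scaled = matrix.values * factors.reindex(matrix.sample_ids)
    return ExpressionMatrix(scaled, "normalized")


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

def genorm_stability(log2_expr: pd.DataFrame) -> GeNormResult:
    """Stability M for each candidate row of a log2 candidate x sample table.

    M_j = mean over partners k != j of SD_samples(log2 x_j - log2 x_k),
    with the sample (n-1) standard deviation. Lower M means a more stable
    reference. Ranking ties break on gene id.
    """
    if log2_expr.shape[0] < 2 or log2_expr.shape[1] < 2:
        raise NormalizationError("geNorm needs >= 2 candidates and >= 2 samples")
    arr = log2_expr.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise NormalizationError("non-finite log2 value among geNorm candidates")
    # pairwise log-ratio SDs
    diffs = arr[:, None, :] - arr[None, :, :]  # (genes, genes, samples)
    sds = diffs.std(axis=2, ddof=1)
    n = arr.shape[0]
    m_values = (sds.sum(axis=1)) / (n - 1)  # diagonal SD is 0
    stability = dict(zip(log2_expr.index, m_values.astype(float)))
    ranked = sorted(stability, key=lambda g: (stability[g], g))
    return GeNormResult(stability_m=stability, ranked_genes=ranked, selected_references=ranked)


def genorm_select(log2_expr: pd.DataFrame, target_count: int) -> GeNormResult:
    """Iteratively drop the least stable candidate until ``target_count`` remain.

    ``ranked_genes`` lists candidates most-to-least stable: survivors (ordered
    by final M) followed by the removed genes in reverse removal order.
    """
    if target_count < 2:
        raise NormalizationError("target_count must be >= 2")
    if target_count > log2_expr.shape[0]:
        raise NormalizationError(
            f"target_count {target_count} exceeds {log2_expr.shape[0]} candidates"
        )
    current = log2_expr.copy()
    removed: list[str] = []
    while current.shape[0] > target_count:
        res = genorm_stability(current)
        worst = max(current.index, key=lambda g: (res.stability_m[g], g))
        removed.append(worst)
        current = current.drop(index=worst)
    final = genorm_stability(current)
    ranked = final.ranked_genes + removed[::-1]
    stability = dict(final.stability_m)
    return GeNormResult(
        stability_m=stability,
        ranked_genes=ranked,
        selected_references=final.ranked_genes,
    )


# ---------------------------------------------------------------------------
# housekeeping normalization
# ---------------------------------------------------------------------------

def housekeeping_normalize(matrix: ExpressionMatrix, references: list[str]) -> ExpressionMatrix:
    """Scale each sample so reference-gene geometric means are equalized.

    factor_s = (mean across samples of the reference geomean) / (reference
    geomean of sample s). Post-condition: the reference geometric mean is
    identical across samples.
    """
    missing = [g for g in references if g not in matrix.values.index]
    if missing:
        raise NormalizationError(f"reference genes absent from matrix: {missing}")
    ref = matrix.values.loc[references].to_numpy(dtype=float)
    if (ref <= 0).any():
        raise NormalizationError("reference gene with zero count; cannot take geometric mean")
    geomeans = _geomean(ref, axis=0)
    factors = geomeans.mean() / geomeans
    scaled = matrix.values * factors
    return ExpressionMatrix(scaled, "normalized")


def normalize_panel(
    matrix: ExpressionMatrix,
    controls: ControlSet,
    n_references: int = 5,
) -> tuple[ExpressionMatrix, dict]:
    """Full panel normalization: positive-control scaling, background
    flagging, geNorm reference selection, housekeeping normalization.

    Returns the normalized matrix (background-excluded genes dropped;
    housekeeping candidates retained for audit) and a report dict.
    """
    factors = positive_factor(controls)
    scaled = apply_factors(matrix, factors)

    threshold = background_threshold(controls)
    kept = background_filter(scaled, threshold)
    kept_set = set(kept) | set(controls.housekeeping_genes)
    filtered = scaled.subset_genes([g for g in scaled.gene_ids if g in kept_set])

    candidates = [g for g in controls.housekeeping_genes if g in filtered.values.index]
    if len(candidates) < 2:
        raise NormalizationError("fewer than 2 housekeeping candidates present after filtering")
    log2_hk = np.log2(filtered.values.loc[candidates] + LOG_OFFSET)
    n_ref = min(n_references, len(candidates))
    n_ref = max(n_ref, 2)
    genorm = genorm_select(log2_hk, n_ref)
    normalized = housekeeping_normalize(filtered, genorm.selected_references)

    report = {
        "positive_factors": factors.to_dict(),
        "background_threshold": threshold,
        "n_genes_retained": len(kept),
        "genorm_ranking": genorm.ranked_genes,
        "selected_references": genorm.selected_references,
        "log_offset": LOG_OFFSET,
    }
    return normalized, report
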