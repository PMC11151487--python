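"""Pair construction, per-pathway standardization and bootstrap training.

Class imbalance is the reason for the pairwise formulation: with hundreds of
primary samples (study + augmentation cohorts) but only a handful of
recurrent ones, the classifier is trained to tell primary-primary (PP) pairs
from primary-recurrent (PR) pairs, multiplying the effective instance count.

Cross-dataset comparability comes from per-sample, per-pathway
standardization: within each pathway's gene list, every sample's expression
vector is scaled to mean 0 / SD 1, so models see only relative expression
patterns among pathway genes.

"Bootstrapping" here is repeated random re-partitioning of *samples* (not
pairs) into train and test sets; pairs are formed within each split so no
sample leaks across the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .nn import ModelSpec, PairConvNet

logger = logging.getLogger(__name__)


class PairError(ValueError):
    pass


@dataclass
class PairDataset:
    """Labelled sample pairs over a fixed gene list.

    ``pairs`` holds (sample_a, sample_b) id tuples; PR pairs are always
    ordered (primary, recurrent). ``labels``: 0 = PP, 1 = PR.
    """

    gene_ids: list[str]
    pairs: list[tuple[str, str]]
    labels: np.ndarray
    split: np.ndarray | None = None  # "train"/"test" per pair, or None if unsplit

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pairs) != len(self.labels):
            raise PairError("pairs and labels length mismatch")

    def features(self, matrix: pd.DataFrame) -> np.ndarray:
        """(n_pairs, genes, 2) feature tensor from a genes x samples frame."""
        sub = matrix.loc[self.gene_ids]
        cols = {s: sub[s].to_numpy(dtype=float) for s in set(c for p in self.pairs for c in p)}
        X = np.empty((len(self.pairs), len(self.gene_ids), 2))
        for i, (a, b) in enumerate(self.pairs):
            X[i, :, 0] = cols[a]
            X[i, :, 1] = cols[b]
        return X

    def subset(self, which: str) -> "PairDataset":
        if self.split is None:
            raise PairError("dataset is unsplit")
        mask = self.split == which
        return PairDataset(
            self.gene_ids,
            [p for p, m in zip(self.pairs, mask) if m],
            self.labels[mask],
        )


@dataclass
class BootstrapResult:
    """One trained bootstrap: model, confusion matrix, metrics, importances."""

    term_id: str
    bootstrap_index: int
    seed: int
    model: PairConvNet
    confusion: dict[str, int]  # tp, fn, tn, fp (PR = positive class)
    metrics: dict[str, float | None]
    importance: pd.Series | None = None  # per-gene aggregated Shapley magnitude


def pathway_znorm(matrix: ExpressionMatrix, gene_set: list[str]) -> pd.DataFrame:
    """Standardize each sample's vector over the pathway's genes to mean 0, SD 1.

    Population SD (ddof = 0). Samples with constant expression over the set
    map to all-zeros, with a log record. Requires >= 2 genes present.
    """
    present = [g for g in gene_set if g in matrix.values.index]
    if len(present) < 2:
        raise PairError(f"fewer than 2 pathway genes present ({len(present)})")
    sub = matrix.values.loc[present]
    arr = sub.to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0)
    const = sd == 0
    if const.any():
        logger.info("pathway_znorm: %d constant sample vectors mapped to zeros", const.sum())
    sd_safe = np.where(const, 1.0, sd)
    z = (arr - mean) / sd_safe
    z[:, const] = 0.0
    return pd.DataFrame(z, index=present, columns=sub.columns)


def build_pairs(primary_ids: list[str], recurrent_ids: list[str], gene_ids: list[str]) -> PairDataset:
    """All PP pairs (label 0) and all PR pairs (label 1): C(P,2) + P*R instances."""
    overlap = set(primary_ids) & set(recurrent_ids)
    if overlap:
        raise PairError(f"ids in both primary and recurrent lists: {sorted(overlap)}")
    if not recurrent_ids:
        raise PairError("no recurrent samples: positive class is empty")
    pp = list(combinations(primary_ids, 2))
    pr = [(p, r) for p in primary_ids for r in recurrent_ids]
    labels = np.array([0] * len(pp) + [1] * len(pr))
    return PairDataset(list(gene_ids), pp + pr, labels)


def split_then_pair(
    primary_ids: list[str],
    recurrent_ids: list[str],
    gene_ids: list[str],
    test_fraction: float,
    seed: int,
) -> PairDataset:
    """Partition samples (stratified by tissue class) before pairing.

    Pairs are formed within each split, so train and test share no sample.
    Both splits must receive at least one recurrent sample.
    """
    if not 0 < test_fraction < 1:
        raise PairError("test_fraction must lie in (0, 1)")
    if len(recurrent_ids) < 2:
        raise PairError("need >= 2 recurrent samples so both splits contain the positive class")
    rng = np.random.default_rng(seed)

    def split(ids: list[str]) -> tuple[list[str], list[str]]:
        ids = list(ids)
        perm = rng.permutation(len(ids))
        n_test = int(round(test_fraction * len(ids)))
        test = [ids[i] for i in sorted(perm[:n_test])]
        train = [ids[i] for i in sorted(perm[n_test:])]
        return train, test

    p_train, p_test = split(primary_ids)
    r_train, r_test = split(recurrent_ids)
    if not r_train or not r_test:
        raise PairError(
            "a split received zero recurrent samples; adjust test_fraction "
            f"(got {len(r_train)} train / {len(r_test)} test recurrents)"
        )
    if len(p_train) < 2 or len(p_test) < 2:
        raise PairError("each split needs >= 2 primary samples to form PP pairs")
    train = build_pairs(p_train, r_train, gene_ids)
    test = build_pairs(p_test, r_test, gene_ids)
    return PairDataset(
        list(gene_ids),
        train.pairs + test.pairs,
        np.concatenate([train.labels, test.labels]),
        split=np.array(["train"] * len(train.pairs) + ["test"] * len(test.pairs)),
    )


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float | None]:
    """Accuracy/sensitivity/specificity/precision from a confusion matrix.

    Ratios with zero denominators are reported as None (missing), never 0.
    """
    total = tp + fn + tn + fp
    def ratio(num, den):
        return num / den if den > 0 else None
    return {
        "accuracy": ratio(tp + tn, total),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "precision": ratio(tp, tp + fp),
    }


def train_pathway_model(
    dataset: PairDataset,
    matrix: pd.DataFrame,
    spec: ModelSpec,
    seed: int,
    term_id: str = "",
    bootstrap_index: int = 0,
) -> BootstrapResult:
    """Train one bootstrap on a split PairDataset and score its test pairs.

    The test pair set is rebalanced before scoring (PP pairs subsampled to
    ``spec.pp_pr_ratio`` times the PR count, seeded): accuracy against a
    PP-dominated pair set would reward the degenerate always-PP predictor,
    making the high-performer threshold meaningless.
    """
    train = dataset.subset("train")
    test = dataset.subset("test")
    for name, ds in (("train", train), ("test", test)):
        if len(set(ds.labels)) < 2:
            raise PairError(f"{name} split lacks a class")
    model = PairConvNet(spec, seed=seed)
    model.fit(train.features(matrix), train.labels, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    pp_idx = np.flatnonzero(test.labels == 0)
    pr_idx = np.flatnonzero(test.labels == 1)
    n_pp = min(len(pp_idx), max(1, int(round(spec.pp_pr_ratio * len(pr_idx)))))
    keep = np.sort(np.concatenate([rng.choice(pp_idx, size=n_pp, replace=False), pr_idx]))
    test = PairDataset(test.gene_ids, [test.pairs[i] for i in keep], test.labels[keep])
    pred = model.predict(test.features(matrix))
    y = test.labels
    confusion = {
        "tp": int(((pred == 1) & (y == 1)).sum()),
        "fn": int(((pred == 0) & (y == 1)).sum()),
        "tn": int(((pred == 0) & (y == 0)).sum()),
        "fp": int(((pred == 1) & (y == 0)).sum()),
    }
    return BootstrapResult(
        term_id=term_id,
        bootstrap_index=bootstrap_index,
        seed=seed,
        model=model,
        confusion=confusion,
        metrics=confusion_metrics(**confusion),
    )


def metric_summary(results: list[BootstrapResult]) -> dict[str, float]:
    """Medians of each test metric across bootstraps (and terms, if mixed).

    Missing (undefined-ratio) metrics are excluded from the medians, with a
    log record of how many were dropped.
    """
    if not results:
        raise PairError("no bootstrap results to summarize")
    out = {}
    for metric in ("accuracy", "sensitivity", "specificity", "precision"):
        vals = [r.metrics[metric] for r in results]
        present = [v for v in vals if v is not None]
        if len(present) < len(vals):
            logger.info("metric_summary: %d missing %s values excluded", len(vals) - len(present), metric)
        out[metric] = float(np.median(present)) if present else float("nan")
    return out
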