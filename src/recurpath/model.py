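"""Model/Results facade for the pathway-centric pairwise classifier stage.

``RecurrenceSignatureModel`` is built from an expression matrix, sample
metadata and a curated term selection; ``fit()`` trains, per term, the
bootstrapped pairwise convolutional classifiers, computes Shapley gene
importances on each bootstrap's test pairs, applies the consensus rule, and
returns a ``RecurrenceSignatureResults`` carrying the per-bootstrap metrics,
the consensus selections, the gene discriminant table and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .consensus import ConsensusSelection, consensus_select, discriminant_scores
from .enrichment import TermSelection
from .io import ExpressionMatrix
from .nn import ModelSpec
from .pairs import (
    BootstrapResult,
    PairError,
    metric_summary,
    pathway_znorm,
    split_then_pair,
    train_pathway_model,
)
from .shapley import aggregate_importance, sampling_shapley

logger = logging.getLogger(__name__)


class RecurrenceSignatureModel:
    """Pathway-centric pairwise classification of recurrence.

    Parameters
    ----------
    expression : ExpressionMatrix
        Merged (study + augmentation) expression on a common gene space.
        Any scale; each term's submatrix is standardized per sample before
        training.
    metadata : pd.DataFrame
        Sample metadata with ``sample_id`` and ``tissue_class`` columns.
    terms : list[TermSelection]
        Curated pathway/GO terms with their DE-gene feature lists.
    config : PipelineConfig
        Thresholds and training hyper-parameters.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        metadata: pd.DataFrame,
        terms: list[TermSelection],
        config: PipelineConfig | None = None,
    ):
        if not terms:
            raise ValueError("no curated terms to model")
        self.expression = expression
        self.metadata = metadata.reset_index(drop=True)
        self.terms = terms
        self.config = config or PipelineConfig()
        sample_set = set(expression.sample_ids)
        meta = self.metadata[self.metadata["sample_id"].isin(sample_set)]
        self.primary_ids = meta.loc[meta["tissue_class"] == "primary", "sample_id"].tolist()
        self.recurrent_ids = meta.loc[meta["tissue_class"] == "recurrent", "sample_id"].tolist()
        if len(self.recurrent_ids) < 2:
            raise ValueError("need >= 2 recurrent samples in the expression matrix")

    @classmethod
    def from_dataframes(
        cls,
        values: pd.DataFrame,
        metadata: pd.DataFrame,
        terms: list[TermSelection],
        scale_tag: str = "normalized",
        config: PipelineConfig | None = None,
    ) -> "RecurrenceSignatureModel":
        return cls(ExpressionMatrix(values, scale_tag), metadata, terms, config)

    # ------------------------------------------------------------------
    def _fit_term(self, term: TermSelection, base_seed: int) -> list[BootstrapResult]:
        cfg = self.config
        znormed = pathway_znorm(self.expression, list(term.genes))
        genes = list(znormed.index)
        spec = ModelSpec(
            n_genes=len(genes),
            epochs=cfg.epochs,
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            pp_pr_ratio=cfg.pp_pr_ratio,
        )
        results = []
        for b in range(cfg.n_bootstraps):
            seed = base_seed + b
            dataset = split_then_pair(
                self.primary_ids, self.recurrent_ids, genes, cfg.test_fraction, seed
            )
            result = train_pathway_model(
                dataset, znormed, spec, seed=seed, term_id=term.term_id, bootstrap_index=b
            )
            test = dataset.subset("test")
            X_test = test.features(znormed)
            train = dataset.subset("train")
            X_train = train.features(znormed)
            rng = np.random.default_rng(seed + 7)
            n_inst = min(cfg.shap_max_instances, X_test.shape[0])
            inst_idx = rng.choice(X_test.shape[0], size=n_inst, replace=False)
            bg_idx = rng.choice(X_train.shape[0], size=min(25, X_train.shape[0]), replace=False)
            values, _ = sampling_shapley(
                result.model.predict_proba,
                X_test[inst_idx],
                X_train[bg_idx],
                n_perm=cfg.shap_permutations,
                seed=seed + 11,
            )
            result.importance = pd.Series(aggregate_importance(values), index=genes)
            results.append(result)
        return results

    def fit(self, seed: int | None = None) -> "RecurrenceSignatureResults":
        """Train all per-term bootstraps and derive the consensus signature.

        All randomness (splits, initialization, PP subsampling, Shapley
        permutations) is derived from ``seed`` (default: config.seed), so a
        repeated fit reproduces identical results.
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        bootstrap_results: dict[str, list[BootstrapResult]] = {}
        selections: list[ConsensusSelection] = []
        for t_idx, term in enumerate(self.terms):
            base_seed = seed + 1000 * t_idx
            try:
                results = self._fit_term(term, base_seed)
            except PairError as exc:
                raise PairError(f"term {term.term_id}: {exc}") from exc
            bootstrap_results[term.term_id] = results
            selections.append(
                consensus_select(
                    results,
                    category=term.category,
                    accuracy_cutoff=cfg.accuracy_cutoff,
                    shap_cutoff=cfg.shap_cutoff,
                    fraction=cfg.consensus_fraction,
                )
            )
        return RecurrenceSignatureResults(self, seed, bootstrap_results, selections)


@dataclass
class RecurrenceSignatureResults:
    """Fitted results: bootstrap metrics, consensus selections, signature."""

    model: RecurrenceSignatureModel
    seed: int
    bootstrap_results: dict[str, list[BootstrapResult]]
    selections: list[ConsensusSelection]
    _discriminant: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def metrics_table(self) -> pd.DataFrame:
        rows = []
        cat = {t.term_id: t.category for t in self.model.terms}
        for term_id, results in self.bootstrap_results.items():
            for r in results:
                rows.append(
                    {
                        "term_id": term_id,
                        "category": cat[term_id],
                        "bootstrap": r.bootstrap_index,
                        "seed": r.seed,
                        **r.confusion,
                        **{k: (np.nan if v is None else v) for k, v in r.metrics.items()},
                    }
                )
        return pd.DataFrame(rows)

    def term_medians(self) -> pd.DataFrame:
        rows = []
        for term_id, results in self.bootstrap_results.items():
            med = metric_summary(results)
            rows.append({"term_id": term_id, **med})
        return pd.DataFrame(rows)

    def overall_medians(self, category: str | None = None) -> dict[str, float]:
        cat = {t.term_id: t.category for t in self.model.terms}
        results = [
            r
            for term_id, rs in self.bootstrap_results.items()
            for r in rs
            if category is None or cat[term_id] == category
        ]
        return metric_summary(results)

    def discriminant_table(self, top_n: int = 0) -> pd.DataFrame:
        if self._discriminant is None:
            self._discriminant = discriminant_scores(self.selections, top_n=0)
        return self._discriminant.head(top_n) if top_n else self._discriminant

    def signature(self, top_n: int = 20) -> list[str]:
        """The top-n genes by discriminant score — the recurrence signature."""
        return self.discriminant_table(top_n)["gene"].tolist()

    def consensus_table(self) -> pd.DataFrame:
        rows = []
        for sel in self.selections:
            for _, row in sel.table.iterrows():
                rows.append(
                    {
                        "term_id": sel.term_id,
                        "category": sel.category,
                        "high_performers": sel.high_performers,
                        "required": sel.required,
                        "gene": row["gene"],
                        "pass_count": row["pass_count"],
                        "mean_importance": row["mean_importance"],
                        "selected": bool(row["selected"]),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self, top_n: int = 20) -> str:
        """Human-readable fit summary."""
        lines = []
        cfg = self.model.config
        lines.append("Pathway-centric pairwise recurrence classifier")
        lines.append("=" * 56)
        lines.append(
            f"terms: {len(self.model.terms)}  bootstraps/term: {cfg.n_bootstraps}  seed: {self.seed}"
        )
        lines.append(
            f"samples: {len(self.model.primary_ids)} primary, "
            f"{len(self.model.recurrent_ids)} recurrent"
        )
        for cat, label in (("pathway", "pathway models"), ("go_bp", "GO-term models")):
            if any(t.category == cat for t in self.model.terms):
                med = self.overall_medians(cat)
                lines.append(
                    f"{label}: median accuracy {med['accuracy']:.3f}, "
                    f"sensitivity {med['sensitivity']:.3f}, specificity {med['specificity']:.3f}"
                )
        n_selected = sum(int(sel.table["selected"].sum()) for sel in self.selections)
        lines.append(f"consensus-selected (term, gene) pairs: {n_selected}")
        table = self.discriminant_table(top_n)
        if len(table):
            lines.append(f"top {min(top_n, len(table))} signature genes by discriminant score:")
            lines.append(
                table[["rank", "gene", "score", "pathway_count", "go_count"]]
                .to_string(index=False)
            )
        else:
            lines.append("no genes passed the consensus rule")
        return "\n".join(lines)
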