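import numpy as np
import pandas as pd
import pytest

from recurpath.io import ExpressionMatrix
from recurpath.nn import ModelSpec, PairConvNet
from recurpath.pairs import (
    PairError,
    build_pairs,
    confusion_metrics,
    metric_summary,
    pathway_znorm,
    split_then_pair,
    train_pathway_model,
)


class TestPathwayZnorm:
    def test_per_sample_mean_zero_sd_one(self, small_matrix):
        genes = small_matrix.gene_ids[:10]
        z = pathway_znorm(small_matrix, genes)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=0), 1.0, atol=1e-12)

    def test_three_value_hand_computation(self):
        df = pd.DataFrame({"S": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        z = pathway_znorm(ExpressionMatrix(df, "normalized"), ["a", "b", "c"])
        expected = np.array([-np.sqrt(1.5), 0.0, np.sqrt(1.5)])
        np.testing.assert_allclose(z["S"].to_numpy(), expected, atol=1e-12)

    def test_scale_invariance_per_sample(self, small_matrix):
        genes = small_matrix.gene_ids[:8]
        z1 = pathway_znorm(small_matrix, genes)
        scaled = ExpressionMatrix(small_matrix.values * 10.0, "normalized")
        z2 = pathway_znorm(scaled, genes)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)

    def test_constant_sample_maps_to_zeros(self):
        df = pd.DataFrame({"S1": [2.0, 2.0, 2.0], "S2": [1.0, 2.0, 3.0]}, index=list("abc"))
        z = pathway_znorm(ExpressionMatrix(df, "normalized"), list("abc"))
        np.testing.assert_allclose(z["S1"], 0.0)

    def test_fewer_than_two_genes_rejected(self, small_matrix):
        with pytest.raises(PairError):
            pathway_znorm(small_matrix, [small_matrix.gene_ids[0]])


class TestBuildPairs:
    def test_small_counts(self):
        ds = build_pairs(["p1", "p2", "p3"], ["r1", "r2"], ["g1", "g2"])
        assert (ds.labels == 0).sum() == 3  # C(3,2)
        assert (ds.labels == 1).sum() == 6  # 3*2

    def test_study_scale_counts(self):
        prim = [f"p{i}" for i in range(367)]
        rec = [f"r{i}" for i in range(7)]
        ds = build_pairs(prim, rec, ["g"])
        assert (ds.labels == 0).sum() == 67161  # C(367,2)
        assert (ds.labels == 1).sum() == 2569  # 367*7

    def test_pr_pairs_ordered_primary_first(self):
        ds = build_pairs(["p1"], ["r1"], ["g"])
        pr = [p for p, l in zip(ds.pairs, ds.labels) if l == 1]
        assert pr == [("p1", "r1")]

    def test_overlapping_lists_rejected(self):
        with pytest.raises(PairError):
            build_pairs(["a", "b"], ["b"], ["g"])

    def test_empty_recurrent_rejected(self):
        with pytest.raises(PairError):
            build_pairs(["a", "b"], [], ["g"])


class TestSplitThenPair:
    def test_no_sample_leakage(self):
        prim = [f"p{i}" for i in range(10)]
        rec = [f"r{i}" for i in range(4)]
        ds = split_then_pair(prim, rec, ["g"], test_fraction=0.5, seed=3)
        train_samples = {s for p in ds.subset("train").pairs for s in p}
        test_samples = {s for p in ds.subset("test").pairs for s in p}
        assert train_samples.isdisjoint(test_samples)

    def test_reproducible_with_seed(self):
        prim = [f"p{i}" for i in range(10)]
        rec = [f"r{i}" for i in range(4)]
        a = split_then_pair(prim, rec, ["g"], 0.5, seed=11)
        b = split_then_pair(prim, rec, ["g"], 0.5, seed=11)
        assert a.pairs == b.pairs and (a.split == b.split).all()

    def test_pair_counts_match_realized_split(self):
        prim = [f"p{i}" for i in range(12)]
        rec = [f"r{i}" for i in range(5)]
        ds = split_then_pair(prim, rec, ["g"], 0.25, seed=2)
        for which in ("train", "test"):
            sub = ds.subset(which)
            p = {s for pair, l in zip(sub.pairs, sub.labels) if l == 0 for s in pair}
            p |= {pair[0] for pair, l in zip(sub.pairs, sub.labels) if l == 1}
            r = {pair[1] for pair, l in zip(sub.pairs, sub.labels) if l == 1}
            P, R = len(p), len(r)
            assert (sub.labels == 0).sum() == P * (P - 1) // 2
            assert (sub.labels == 1).sum() == P * R

    def test_single_recurrent_rejected(self):
        with pytest.raises(PairError):
            split_then_pair(["p1", "p2", "p3"], ["r1"], ["g"], 0.5, seed=0)


class TestConfusionMetrics:
    def test_hand_computed_ratios(self):
        m = confusion_metrics(tp=9, fn=1, tn=27, fp=1)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(27 / 28)
        assert m["accuracy"] == pytest.approx(36 / 38)

    def test_perfect_prediction(self):
        m = confusion_metrics(tp=5, fn=0, tn=5, fp=0)
        assert all(v == 1.0 for v in m.values())

    def test_zero_denominator_reported_missing(self):
        m = confusion_metrics(tp=0, fn=2, tn=3, fp=0)
        assert m["precision"] is None


def _planted_dataset(n_prim=30, n_rec=6, n_genes=12, shift=3.0, seed=0):
    rng = np.random.default_rng(seed)
    prim = [f"p{i}" for i in range(n_prim)]
    rec = [f"r{i}" for i in range(n_rec)]
    genes = [f"g{i}" for i in range(n_genes)]
    vals = rng.normal(0, 1, size=(n_genes, n_prim + n_rec))
    vals[: n_genes // 2, n_prim:] += shift
    matrix = pd.DataFrame(vals, index=genes, columns=prim + rec)
    ds = split_then_pair(prim, rec, genes, 0.3, seed=seed)
    return ds, matrix


class TestTraining:
    def test_separable_signal_reaches_high_accuracy(self):
        ds, matrix = _planted_dataset(shift=3.0, seed=1)
        spec = ModelSpec(n_genes=12, epochs=80)
        result = train_pathway_model(ds, matrix, spec, seed=1)
        assert result.metrics["accuracy"] >= 0.95

    def test_permuted_labels_stay_near_chance(self):
        accs = []
        for seed in range(5):
            ds, matrix = _planted_dataset(shift=0.0, seed=seed)
            spec = ModelSpec(n_genes=12, epochs=40)
            result = train_pathway_model(ds, matrix, spec, seed=seed)
            accs.append(result.metrics["accuracy"])
        assert 0.35 <= float(np.mean(accs)) <= 0.65

    def test_same_seed_identical_metrics(self):
        ds, matrix = _planted_dataset(seed=4)
        spec = ModelSpec(n_genes=12, epochs=30)
        r1 = train_pathway_model(ds, matrix, spec, seed=9)
        r2 = train_pathway_model(ds, matrix, spec, seed=9)
        assert r1.confusion == r2.confusion
        assert r1.metrics == r2.metrics

    def test_metric_summary_matches_direct_median(self):
        ds, matrix = _planted_dataset(seed=2)
        spec = ModelSpec(n_genes=12, epochs=30)
        results = [train_pathway_model(ds, matrix, spec, seed=s) for s in range(3)]
        summary = metric_summary(results)
        accs = [r.metrics["accuracy"] for r in results]
        assert summary["accuracy"] == pytest.approx(float(np.median(accs)))
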