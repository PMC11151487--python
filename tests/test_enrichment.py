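import numpy as np
import pandas as pd
import pytest
from math import comb

from recurpath.diffexpr import bh_qvalues
from recurpath.enrichment import (
    EnrichmentError,
    bridge_genes,
    curate_for_dl,
    hypergeom_enrich,
    report_terms,
)
from recurpath.io import GeneSet, GeneSetCollection


def brute_force_tail(N, K, n, k):
    """P(X >= k) for X ~ Hypergeom(N, K, n) by direct summation."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x) * comb(N - K, n - x) / comb(N, n)
    return total


def collection_of(*sets):
    return GeneSetCollection([GeneSet(*s) for s in sets])


class TestHypergeomEnrich:
    def test_full_overlap_hand_example(self):
        # N=20, K=5, n=5, k=5 -> 1 / C(20,5)
        universe = [f"g{i}" for i in range(20)]
        de = universe[:5]
        col = collection_of(("T", "t", "pathway", tuple(universe[:5])))
        res = hypergeom_enrich(de, universe, col)
        assert res.loc[0, "p_value"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        col = collection_of(("T", "t", "pathway", tuple(universe[10:15])))
        res = hypergeom_enrich(universe[:5], universe, col)
        assert res.loc[0, "k"] == 0
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_de_gene_outside_universe_rejected(self):
        col = collection_of(("T", "t", "pathway", ("a", "b")))
        with pytest.raises(EnrichmentError):
            hypergeom_enrich(["zzz"], ["a", "b"], col)

    def test_matches_brute_force_tail_sum(self, rng):
        for _ in range(200):
            N = int(rng.integers(10, 60))
            universe = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            term = list(rng.choice(universe, size=K, replace=False))
            de = list(rng.choice(universe, size=n, replace=False))
            res = hypergeom_enrich(de, universe, collection_of(("T", "t", "pathway", tuple(term))))
            k = res.loc[0, "k"]
            expected = brute_force_tail(N, K, n, k)
            assert res.loc[0, "p_value"] == pytest.approx(expected, rel=1e-12)

    def test_gene_relabelling_leaves_p_unchanged(self, rng):
        universe = [f"g{i}" for i in range(30)]
        term = universe[:10]
        de = universe[5:15]
        res1 = hypergeom_enrich(de, universe, collection_of(("T", "t", "pathway", tuple(term))))
        mapping = dict(zip(universe, rng.permutation(universe)))
        res2 = hypergeom_enrich(
            [mapping[g] for g in de],
            universe,
            collection_of(("T", "t", "pathway", tuple(mapping[g] for g in term))),
        )
        assert res1.loc[0, "p_value"] == pytest.approx(res2.loc[0, "p_value"], rel=1e-12)

    def test_null_de_sets_are_calibrated(self, rng):
        """Random DE sets: BH-adjusted discoveries stay near the nominal rate."""
        universe = [f"g{i}" for i in range(300)]
        col = collection_of(
            *[("T%d" % t, "t", "pathway",
               tuple(rng.choice(universe, size=30, replace=False))) for t in range(20)]
        )
        flagged, total = 0, 0
        for _ in range(200):
            de = list(rng.choice(universe, size=25, replace=False))
            res = hypergeom_enrich(de, universe, col)
            flagged += int((res["adj_p"] < 0.05).sum())
            total += len(res)
        assert flagged / total <= 0.08


class TestReportAndCuration:
    def make_result(self, rows):
        df = pd.DataFrame(rows, columns=["term_id", "category", "k", "p_value", "overlap_genes"])
        df["term_name"] = df["term_id"]
        df["adj_p"] = np.nan
        for cat, idx in df.groupby("category").groups.items():
            df.loc[idx, "adj_p"] = bh_qvalues(df.loc[idx, "p_value"].to_numpy())
        return df

    def test_empty_result_reports_empty(self):
        assert len(report_terms(pd.DataFrame())) == 0

    def test_truncation_to_top_n(self):
        rows = [[f"T{i}", "pathway", 5, 1e-8 * (i + 1), "a,b,c,d,e"] for i in range(12)]
        rep = report_terms(self.make_result(rows), "pathway", adj_cutoff=0.001, top_n=10)
        assert len(rep) == 10
        assert rep.loc[0, "term_id"] == "T0"

    def test_curation_floors_differ_by_category(self):
        rows = [
            ["P_small", "pathway", 4, 1e-6, "a,b,c,d"],
            ["P_ok", "pathway", 9, 1e-6, ",".join("abcdefghi")],
            ["G_small", "go_bp", 9, 1e-6, ",".join("abcdefghi")],
            ["G_ok", "go_bp", 10, 1e-6, ",".join("abcdefghij")],
        ]
        sel = curate_for_dl(self.make_result(rows))
        ids = {s.term_id for s in sel}
        assert ids == {"P_ok", "G_ok"}

    def test_counts_of_qualifying_terms(self):
        rows = (
            [[f"P{i}", "pathway", 6, 1e-6, ",".join("abcdef")] for i in range(3)]
            + [[f"G{i}", "go_bp", 11, 1e-6, ",".join("abcdefghijk")] for i in range(2)]
            + [["null", "pathway", 6, 0.9, ",".join("abcdef")]]
        )
        sel = curate_for_dl(self.make_result(rows))
        assert len(sel) == 5

    def test_curation_nested_in_report_tier(self):
        rows = [[f"P{i}", "pathway", 8, 1e-9, ",".join("abcdefgh")] for i in range(6)]
        result = self.make_result(rows)
        report_ids = set(report_terms(result, "pathway", adj_cutoff=0.05, top_n=100)["term_id"])
        assert {s.term_id for s in curate_for_dl(result)} <= report_ids


class TestBridgeGenes:
    def make_result(self, overlaps_by_term):
        rows = []
        for i, (term_id, cat, genes) in enumerate(overlaps_by_term):
            rows.append([term_id, cat, len(genes), 1e-8 * (i + 1), ",".join(genes)])
        df = pd.DataFrame(rows, columns=["term_id", "category", "k", "p_value", "overlap_genes"])
        df["term_name"] = df["term_id"]
        df["adj_p"] = df["p_value"]
        return df

    def test_planted_link_counts(self):
        bridge = [f"B{i}" for i in range(3)]  # in 5+ of the 10 terms
        passenger = ["x", "y"]
        terms = []
        for i in range(5):
            terms.append((f"P{i}", "pathway", bridge + passenger[: i % 2]))
        for i in range(5):
            genes = bridge if i < 2 else ["y"]
            terms.append((f"G{i}", "go_bp", genes))
        rep = bridge_genes(self.make_result(terms), min_links=5)
        assert rep.bridge_genes["gene"].tolist() == bridge
        assert (rep.bridge_genes["n_links"] >= 5).all()

    def test_gene_in_four_terms_excluded(self):
        terms = [(f"P{i}", "pathway", ["g"] if i < 4 else ["h"]) for i in range(5)]
        terms += [(f"G{i}", "go_bp", ["h"]) for i in range(5)]
        rep = bridge_genes(self.make_result(terms), min_links=5)
        assert "g" not in rep.bridge_genes["gene"].tolist()
        assert "h" in rep.bridge_genes["gene"].tolist()  # 1 + 5 = 6 links

    def test_only_top5_terms_per_category_used(self):
        # gene appears only in low-ranked pathways beyond the top 5
        terms = [(f"P{i}", "pathway", ["top"]) for i in range(5)]
        terms += [(f"P{i+5}", "pathway", ["late"]) for i in range(5)]
        terms += [(f"G{i}", "go_bp", ["top"]) for i in range(5)]
        rep = bridge_genes(self.make_result(terms), min_links=5)
        assert rep.bridge_genes["gene"].tolist() == ["top"]
        assert set(rep.links["term_id"]) == {f"P{i}" for i in range(5)} | {f"G{i}" for i in range(5)}
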