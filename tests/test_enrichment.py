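"""Gene mapping, hypergeometric/permutation enrichment, SGO-KGO scoring."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from esam_methpipe.enrichment import (
    context_enrichment,
    dunn_pairwise,
    effect_by_context,
    efo_permutation,
    efo_score,
    hpo_overlap_z,
    map_genes,
    sgo_kgo_score,
)


class TestMapGenes:
    GENES = pd.DataFrame(
        {
            "gene": ["A", "B", "C", "D", "E"],
            "chromosome": ["chr1", "chr1", "chr1", "chr2", "chr1"],
            "start": [1_000, 40_000, 95_000, 1_000, 200_000],
            "end": [5_000, 45_000, 96_000, 5_000, 210_000],
        }
    )

    def _cluster_set(self, spans):
        from esam_methpipe.clusters import ClusterSet

        df = pd.DataFrame(spans, columns=["chromosome", "start", "end"])
        df.index = [f"c{i}" for i in range(len(df))]
        members = pd.Series(dtype=object)
        return ClusterSet(clusters=df, members=members)

    def test_distance_boundary(self):
        # gene A ends at 5,000; span starting at 15,000 is exactly 10 kb away
        cs = self._cluster_set([("chr1", 15_000, 15_100)])
        gm = map_genes(cs, genes=self.GENES)
        assert "A" in gm.mapping["c0"]
        cs2 = self._cluster_set([("chr1", 15_001, 15_100)])
        gm2 = map_genes(cs2, genes=self.GENES)
        assert "A" not in gm2.mapping["c0"]

    def test_cluster_inside_gene_body(self):
        cs = self._cluster_set([("chr1", 41_000, 42_000)])
        gm = map_genes(cs, genes=self.GENES)
        assert gm.mapping["c0"] == ("B",)

    def test_hand_enumeration(self):
        cs = self._cluster_set(
            [("chr1", 4_000, 50_000), ("chr2", 2_000, 2_100), ("chr1", 150_000, 160_000)]
        )
        gm = map_genes(cs, genes=self.GENES)
        # A (1-5 kb) and B (40-45 kb) touch the padded span [ -6, 60 ] kb;
        # C starts 45 kb past the span end, D is the only chr2 gene,
        # E (200-210 kb) is 40 kb past the third span
        assert gm.mapping == {"c0": ("A", "B"), "c1": ("D",), "c2": ()}


class TestContextEnrichment:
    def test_extreme_subset(self):
        bg = ["Body"] * 50 + ["TSS200"] * 50
        sel = ["Body"] * 20
        tab = context_enrichment(sel, bg)
        assert tab.loc["Body", "p_enrich"] == tab["p_enrich"].min()
        assert tab.loc["TSS200", "p_deplete"] == tab["p_deplete"].min()

    def test_matches_brute_force_sum(self):
        # small universe: compare tails against explicit pmf sums
        bg = ["Body"] * 8 + ["TSS200"] * 6
        sel = ["Body"] * 5 + ["TSS200"] * 1
        tab = context_enrichment(sel, bg)
        N, K, n, k = 14, 8, 6, 5
        pmf = [
            math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
            for x in range(0, min(K, n) + 1)
        ]
        assert tab.loc["Body", "p_enrich"] == pytest.approx(sum(pmf[k:]), rel=1e-10)
        assert tab.loc["Body", "p_deplete"] == pytest.approx(sum(pmf[: k + 1]), rel=1e-10)

    def test_uniform_subset_calibrated(self):
        rng = np.random.default_rng(0)
        bg = list(rng.choice(["Body", "TSS200", "IGR"], size=3_000, p=[0.5, 0.3, 0.2]))
        pvals = []
        for _ in range(100):
            sel = rng.choice(bg, size=60, replace=False)
            tab = context_enrichment(sel, bg)
            pvals.append(tab.loc["Body", "p_enrich"])
        # roughly uniform: mid-quantile behaviour
        assert 0.3 < np.mean(np.array(pvals) < 0.5) < 0.7


CATALOG = pd.DataFrame(
    [
        ("EFO:1", "height", "g0", 3, "anthro"),
        ("EFO:1", "height", "g1", 1, "anthro"),
        ("EFO:1", "height", "g2", 2, "anthro"),
        ("EFO:2", "bmi", "g1", 4, "anthro"),
        ("EFO:2", "bmi", "g3", 2, "anthro"),
        ("EFO:3", "t2d", "g4", 5, "metab"),
        ("EFO:4", "lipids", "g5", 1, "metab"),
        ("EFO:4", "lipids", "g6", 2, "metab"),
    ],
    columns=["efo_id", "efo_label", "gene", "snp_count", "parent_efo"],
)


class TestEfo:
    def test_score_requires_two_genes(self):
        tab = efo_score(["g0", "g1", "g4"], CATALOG)
        assert set(tab["efo_id"]) == {"EFO:1"}  # EFO:3 has one candidate only
        assert sorted(tab["snp_count"]) == [1, 3]

    def test_score_empty_when_no_catalog_overlap(self):
        assert efo_score(["zz"], CATALOG).empty

    def test_score_matches_independent_join(self):
        cand = ["g1", "g2", "g3", "g5", "g6"]
        tab = efo_score(cand, CATALOG)
        merged = CATALOG.merge(pd.DataFrame({"gene": cand}), on="gene")
        counts = merged.groupby("efo_id")["gene"].nunique()
        expected = merged[merged["efo_id"].isin(counts.index[counts >= 2])]
        assert len(tab) == len(expected)
        assert set(map(tuple, tab[["efo_id", "gene"]].values)) == set(
            map(tuple, expected[["efo_id", "gene"]].values)
        )

    def test_universe_equals_candidates_p_one(self):
        cand = ["g0", "g1", "g2"]
        res = efo_permutation(cand, cand, CATALOG, n_perms=100, seed=0)
        assert res.empirical_p == 1.0

    def test_empty_catalog_p_one(self):
        empty = CATALOG.iloc[:0]
        res = efo_permutation(["g0"], ["g0", "g1"], empty, n_perms=50, seed=0)
        assert res.g_obs == 0 and res.empirical_p == 1.0

    def test_matches_exhaustive_enumeration(self):
        """12-gene universe: empirical joint-tail probability agrees with
        exact enumeration over all candidate draws."""
        universe = [f"g{i}" for i in range(12)]
        cand = ["g0", "g1", "g3", "g4", "g6"]
        k = len(cand)
        res = efo_permutation(cand, universe, CATALOG, n_perms=6_000, seed=42)

        def stat(draw):
            draw = set(draw)
            in_cat = CATALOG[CATALOG["gene"].isin(draw)]
            g = in_cat["gene"].nunique()
            e = (in_cat.groupby("efo_id")["gene"].nunique() >= 2).sum()
            return g, e

        g_obs, e_obs = stat(cand)
        assert (res.g_obs, res.e_obs) == (g_obs, e_obs)
        total = hits = 0
        for draw in itertools.combinations(universe, k):
            g, e = stat(draw)
            total += 1
            hits += g >= g_obs and e >= e_obs
        exact = hits / total
        mc_sd = math.sqrt(exact * (1 - exact) / 6_000)
        assert res.empirical_p == pytest.approx(exact, abs=max(4 * mc_sd, 0.01))

    def test_candidates_exceed_universe_rejected(self):
        with pytest.raises(ValueError):
            efo_permutation(["a", "b"], ["a"], CATALOG, n_perms=10, seed=0)


class TestHpoOverlap:
    def test_null_z_near_zero(self):
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(200)]
        hpo = universe[:40]
        zs = [
            hpo_overlap_z(
                list(rng.choice(universe, size=30, replace=False)),
                hpo,
                universe,
                n_perms=2_000,
                seed=int(s),
            ).z
            for s in range(20)
        ]
        assert abs(np.mean(zs)) < 0.5

    def test_degenerate_universe_flagged(self):
        hpo = ["a", "b", "c", "d"]
        with pytest.warns(UserWarning, match="degenerate"):
            res = hpo_overlap_z(["a", "b"], hpo, hpo, n_perms=200, seed=0)
        assert res.degenerate and math.isnan(res.z)

    def test_null_moments_match_hypergeometric_closed_form(self):
        # 15-gene universe: resampled null mean/sd vs exact moments
        universe = [f"g{i}" for i in range(15)]
        hpo = universe[:6]
        cand = universe[5:10]
        res = hpo_overlap_z(cand, hpo, universe, n_perms=60_000, seed=7)
        N, K, n = 15, 6, 5
        mean = n * K / N
        var = n * K / N * (N - K) / N * (N - n) / (N - 1)
        assert res.null_mean == pytest.approx(mean, abs=0.02)
        assert res.null_sd == pytest.approx(math.sqrt(var), abs=0.02)


class TestSgoKgo:
    def test_caption_extremes(self):
        sgo_p = pd.Series({"GO:top": 1e-6, "GO:b": 0.2, "GO:c": 0.5, "GO:d": 0.9})
        kgo_p = pd.Series({"GO:top": 1e-5, "GO:x": 0.3, "GO:y": 0.6, "GO:z": 0.8})
        pheno = {"HP:1": ["A", "B"]}
        gmap = {"GO:top": ["A", "B", "C"], "GO:b": [], "GO:c": [], "GO:d": []}
        tab = sgo_kgo_score(sgo_p, kgo_p, pheno, gmap)
        top = tab[(tab["sgo_id"] == "GO:top")].iloc[0]
        # top quartile of both lists, proportion 1 -> final 1
        assert top["final"] == 1.0
        # an SGO absent from the KGO list scores quartile 0
        absent = tab[tab["sgo_id"] == "GO:b"].iloc[0]
        assert absent["quartile_score"] == 0.0
        assert absent["final"] == absent["proportion_score"] / 2

    def test_hand_worksheet_eight_terms(self):
        sgo_p = pd.Series({f"GO:{i}": (i + 1) / 100 for i in range(8)})
        kgo_p = pd.Series({f"GO:{i}": (8 - i) / 100 for i in range(8)})
        # SGO quartiles (ascending p): GO:0,1 -> 1; GO:2,3 -> .75; GO:4,5 -> .5; GO:6,7 -> .25
        # KGO quartiles reversed
        pheno = {"HP:1": ["A", "B", "C", "D"]}
        gmap = {f"GO:{i}": ["A", "B"] if i < 4 else [] for i in range(8)}
        tab = sgo_kgo_score(sgo_p, kgo_p, pheno, gmap).set_index("sgo_id")
        assert tab.loc["GO:0", "quartile_score"] == pytest.approx(1.0 * 0.25)
        assert tab.loc["GO:7", "quartile_score"] == pytest.approx(0.25 * 1.0)
        assert tab.loc["GO:2", "quartile_score"] == pytest.approx(0.75 * 0.5)
        assert tab.loc["GO:0", "proportion_score"] == pytest.approx(0.5)
        assert tab.loc["GO:0", "final"] == pytest.approx((0.25 + 0.5) / 2)

    def test_empty_phenotype_flagged(self):
        tab = sgo_kgo_score(
            pd.Series({"GO:1": 0.1}), pd.Series({"GO:1": 0.1}), {"HP:1": []}, {"GO:1": ["A"]}
        )
        assert tab.iloc[0]["flagged"]

    @given(
        st.lists(st.floats(1e-10, 1.0), min_size=1, max_size=12),
        st.lists(st.floats(1e-10, 1.0), min_size=1, max_size=12),
        st.integers(0, 5),
    )
    def test_final_score_bounded(self, sp, kp, n_genes):
        sgo_p = pd.Series({f"S{i}": v for i, v in enumerate(sp)})
        kgo_names = [f"S{i}" for i in range(0, len(kp), 2)] + [
            f"K{i}" for i in range(1, len(kp), 2)
        ]
        kgo_p = pd.Series(dict(zip(kgo_names, kp)))
        genes = [f"g{i}" for i in range(n_genes)]
        tab = sgo_kgo_score(
            sgo_p, kgo_p, {"HP:1": genes}, {s: genes[: n_genes // 2] for s in sgo_p.index}
        )
        ok = tab[~tab["flagged"]]
        assert ((ok["final"] >= 0) & (ok["final"] <= 1)).all()
        q = ok["quartile_score"]
        assert ((q == 0) | ((q >= 1 / 16) & (q <= 1))).all()


class TestEffectByContext:
    def _results(self, values):
        idx = [f"cg{i}" for i in range(len(values))]
        return pd.DataFrame({"beta_slope": values}, index=idx)

    def test_two_group_dunn_equals_kw(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0.02, 0.01, size=40)
        res = self._results(vals)
        ctx = pd.Series(["Body"] * 20 + ["TSS200"] * 20, index=res.index)
        out = effect_by_context(res, ctx)
        z = out["dunn"].iloc[0]["z"]
        assert z**2 == pytest.approx(out["kruskal_h"], rel=1e-9)

    def test_textbook_kruskal(self):
        # three groups of 4 with no ties: H from the textbook rank formula
        groups = {"A": [1.1, 2.2, 3.3, 9.9], "B": [4.4, 5.5, 6.6, 10.1], "C": [0.1, 7.7, 8.8, 11.1]}
        vals = sum(map(list, groups.values()), [])
        res = self._results(vals)
        ctx = pd.Series(
            ["A"] * 4 + ["B"] * 4 + ["C"] * 4, index=res.index
        )
        out = effect_by_context(res, ctx, signed=True)
        ranks = stats.rankdata(np.abs(vals)) if False else stats.rankdata(vals)
        n = 12
        h = 12 / (n * (n + 1)) * sum(
            len(g) * (np.mean([ranks[i] for i, v in enumerate(vals) if v in g])) ** 2
            for g in groups.values()
        ) - 3 * (n + 1)
        assert out["kruskal_h"] == pytest.approx(h, rel=1e-9)

    def test_permuted_labels_not_significant_typically(self):
        rng = np.random.default_rng(3)
        pvals = []
        base = rng.normal(0.03, 0.01, size=60)
        for _ in range(50):
            res = self._results(base)
            ctx = pd.Series(
                rng.permutation(["Body"] * 30 + ["TSS200"] * 30), index=res.index
            )
            pvals.append(effect_by_context(res, ctx)["kruskal_p"])
        assert 0.2 < np.mean(np.array(pvals) < 0.5) < 0.8

    def test_single_group_rejected(self):
        res = self._results([0.01, 0.02, 0.03])
        ctx = pd.Series(["Body"] * 3, index=res.index)
        with pytest.raises(ValueError):
            effect_by_context(res, ctx)
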