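"""Genotype QC, cis pairing, meQTL models and sensitivity classification."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from esam_methpipe.meqtl import (
    GenotypeMatrix,
    cis_pairs,
    classify_nutrition_sensitive,
    fit_interaction,
    fit_meqtl,
    genotype_qc,
    hwe_exact_test,
    merge_meqtl_fits,
    reference_overlap_fisher,
)
from esam_methpipe.simulate import SimulationConfig, simulate_genotypes, simulate_study


def hwe_oracle(n_het, n_hom_rare, n_hom_common):
    """Exact-rational enumeration of the conditional heterozygote
    distribution; independent of the implementation's log-space path."""
    n = n_het + n_hom_rare + n_hom_common
    rare = 2 * min(n_hom_rare, n_hom_common) + n_het
    common = 2 * n - rare
    if rare == 0:
        return 1.0

    def prob(h):
        hr = (rare - h) // 2
        hc = n - h - hr
        return Fraction(
            math.factorial(n) * 2**h * math.factorial(rare) * math.factorial(common),
            math.factorial(hr)
            * math.factorial(h)
            * math.factorial(hc)
            * math.factorial(2 * n),
        )

    hets = range(rare % 2, rare + 1, 2)
    probs = {h: prob(h) for h in hets}
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHwe:
    def test_perfect_equilibrium_retained(self):
        assert hwe_exact_test(50, 25, 25) > 0.5

    def test_extreme_disequilibrium_tiny_p(self):
        assert hwe_exact_test(0, 50, 50) < 1e-20

    def test_seven_six_seven_matches_enumeration(self):
        assert hwe_exact_test(6, 7, 7) == pytest.approx(hwe_oracle(6, 7, 7), rel=1e-9)

    def test_exhaustive_small_samples(self):
        """All genotype configurations with n <= 20 match the exact-rational
        enumeration oracle."""
        for n in (5, 11, 20):
            for hr in range(0, n + 1):
                for h in range(0, n - hr + 1):
                    hc = n - hr - h
                    assert hwe_exact_test(h, hr, hc) == pytest.approx(
                        hwe_oracle(h, hr, hc), rel=1e-9, abs=1e-12
                    ), (h, hr, hc)

    def test_monomorphic_p_one(self):
        assert hwe_exact_test(0, 0, 30) == 1.0


def _geno(dosage_rows, positions=None, chromosome="chr1", samples=None):
    dos = pd.DataFrame(
        np.asarray(dosage_rows, dtype=float),
        index=[f"rs{i}" for i in range(len(dosage_rows))],
        columns=samples
        if samples is not None
        else [f"S{i:03d}" for i in range(np.asarray(dosage_rows).shape[1])],
    )
    snps = pd.DataFrame(
        {
            "chromosome": chromosome,
            "position": positions if positions is not None else np.arange(len(dos)) * 1000 + 1,
        },
        index=dos.index,
    )
    return GenotypeMatrix(dosages=dos, snps=snps)


class TestGenotypeQc:
    def test_filters_applied(self):
        rng = np.random.default_rng(0)
        good = rng.binomial(2, 0.3, size=100)
        mono = np.zeros(100)
        disequi = np.array([0.0] * 50 + [2.0] * 50)
        rare = rng.binomial(2, 0.01, size=100)
        geno = _geno([good, mono, disequi, rare])
        out, rep = genotype_qc(geno)
        assert list(out.dosages.index) == ["rs0"]
        assert rep.n_removed_hwe == 1 and rep.n_removed_maf == 2

    def test_missingness_filters(self):
        rng = np.random.default_rng(1)
        rows = rng.binomial(2, 0.4, size=(60, 50)).astype(float)
        rows[0, :5] = np.nan  # one SNP 10% missing; per-sample missingness <2%
        geno = _geno(list(rows))
        out, rep = genotype_qc(geno)
        assert rep.n_removed_missing == 1
        assert "rs0" not in out.dosages.index

    def test_excluded_sample_list(self):
        rng = np.random.default_rng(2)
        geno = _geno([rng.binomial(2, 0.4, size=20)])
        out, rep = genotype_qc(geno, excluded_samples=["S000", "S001"])
        assert rep.n_samples_after == 18


class TestCisPairs:
    def _ann(self, positions, chromosome="chr1"):
        return pd.DataFrame(
            {"chromosome": chromosome, "position": positions},
            index=[f"cg{i}" for i in range(len(positions))],
        )

    def test_distance_boundary(self):
        geno = _geno([[0, 1, 2]], positions=[20_000])
        near = cis_pairs(geno, self._ann([10_000]))
        far = cis_pairs(geno, self._ann([9_999]))
        assert len(near) == 1 and near.iloc[0]["distance"] == 10_000
        assert far.empty

    def test_cross_chromosome_never_paired(self):
        geno = _geno([[0, 1, 2]], positions=[500], chromosome="chr2")
        assert cis_pairs(geno, self._ann([500])).empty

    def test_matches_double_loop(self):
        rng = np.random.default_rng(3)
        geno = _geno(
            rng.binomial(2, 0.4, size=(5, 4)), positions=rng.integers(1, 60_000, 5)
        )
        ann = self._ann(rng.integers(1, 60_000, 4))
        got = {
            (r["snp_id"], r["cpg_id"]) for _, r in cis_pairs(geno, ann).iterrows()
        }
        expected = {
            (s, c)
            for s in geno.snps.index
            for c in ann.index
            if abs(geno.snps.loc[s, "position"] - ann.loc[c, "position"]) <= 10_000
        }
        assert got == expected


def _simulate_meqtl_study(seed, n_dc=60, n_dl=25, slope=0.4, kind="interaction"):
    cfg = SimulationConfig(
        n_samples_per_group=n_dc,
        n_dl_samples_per_group=n_dl,
        n_probes=150,
        n_chromosomes=2,
        n_true_dmcs=0,
        n_snps=2,
        maf_range=(0.3, 0.5),
        n_additive_meqtls=2 if kind == "additive" else 0,
        n_interaction_meqtls=2 if kind == "interaction" else 0,
        meqtl_slope_m=slope,
        seed=seed,
    )
    study, truth = simulate_study(cfg)
    geno, doped = simulate_genotypes(cfg, study, truth)
    return doped, geno, truth


class TestFits:
    def test_additive_slope_recovered(self):
        est = []
        for seed in range(10):
            study, geno, truth = _simulate_meqtl_study(100 + seed, kind="additive")
            pairs = truth.meqtl_pairs[["snp_id", "cpg_id"]]
            fits = fit_meqtl(study, geno, pairs, subset={"timepoint": "DC"}, transform=False)
            est.extend(fits["beta1"].tolist())
        assert np.mean(est) == pytest.approx(0.4, abs=0.05)

    def test_permuted_genotypes_null(self):
        study, geno, truth = _simulate_meqtl_study(7, kind="additive")
        rng = np.random.default_rng(0)
        perm = geno.dosages.copy()
        pvals = []
        for _ in range(60):
            perm.iloc[:, :] = rng.permutation(geno.dosages.to_numpy(), axis=1).reshape(
                geno.dosages.shape
            )
            pg = GenotypeMatrix(dosages=perm.copy(), snps=geno.snps)
            fits = fit_meqtl(
                study, pg, truth.meqtl_pairs[["snp_id", "cpg_id"]], subset={"timepoint": "DC"}
            )
            pvals.extend(fits["p_main"].tolist())
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_dosage_untested(self):
        study, geno, truth = _simulate_meqtl_study(8)
        const = geno.dosages.copy()
        const.iloc[0, :] = 1.0
        pg = GenotypeMatrix(dosages=const, snps=geno.snps)
        pairs = truth.meqtl_pairs[["snp_id", "cpg_id"]].iloc[:1]
        fits = fit_meqtl(study, pg, pairs, subset={"timepoint": "DC"})
        assert fits.iloc[0]["status"] == "untested"

    def test_interaction_only_pattern(self):
        study, geno, truth = _simulate_meqtl_study(9, slope=0.6)
        pairs = truth.meqtl_pairs[["snp_id", "cpg_id"]]
        dc = fit_interaction(
            study, geno, pairs, subset={"timepoint": "DC"}, transform=False
        )
        assert (dc["p_interaction"] < 0.05).all()
        # reference (NESAM) slope near zero for interaction-only pairs
        assert np.abs(dc["slope_ref"]).max() < 0.2
        assert np.abs(dc["slope_alt"] - 0.6).max() < 0.25

    def test_constant_group_rejected(self):
        study, geno, truth = _simulate_meqtl_study(10)
        with pytest.raises(ValueError, match="inestimable"):
            fit_interaction(
                study,
                geno,
                truth.meqtl_pairs[["snp_id", "cpg_id"]],
                subset={"timepoint": "DC", "group": "ESAM"},
            )


class TestClassify:
    def _records(self, p_main, p_int_dc, p_int_dl):
        dc = pd.DataFrame(
            {
                "snp_id": ["rs0"],
                "cpg_id": ["cg0"],
                "p_main": [p_main],
                "p_interaction": [p_int_dc],
            }
        )
        dl = pd.DataFrame(
            {"snp_id": ["rs0"], "cpg_id": ["cg0"], "p_interaction": [p_int_dl]}
        )
        return dc, dl

    @pytest.mark.parametrize(
        "p_main,p_dc,p_dl,expected",
        [
            (0.01, 0.01, 0.50, "nutrition_sensitive"),
            (0.01, 0.01, 0.01, "insensitive"),
            (0.01, 0.50, 0.50, "insensitive"),
            (0.50, 0.01, 0.50, "untested"),  # fails the DC meQTL screen
        ],
    )
    def test_rules(self, p_main, p_dc, p_dl, expected):
        dc, dl = self._records(p_main, p_dc, p_dl)
        out = classify_nutrition_sensitive(dc, dl)
        assert out.iloc[0]["classification"] == expected

    def test_stringent_tier(self):
        dc, dl = self._records(0.001, 1e-5, 0.6)
        out = classify_nutrition_sensitive(dc, dl)
        assert bool(out.iloc[0]["stringent"])

    def test_missing_dl_untested(self):
        dc, dl = self._records(0.01, 0.01, 0.5)
        dl = dl.iloc[:0]
        out = classify_nutrition_sensitive(dc, dl)
        assert out.iloc[0]["classification"] == "untested"

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        dc = pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(20)],
                "cpg_id": [f"cg{i}" for i in range(20)],
                "p_main": rng.uniform(size=20),
                "p_interaction": rng.uniform(size=20),
            }
        )
        dl = dc[["snp_id", "cpg_id"]].copy()
        dl["p_interaction"] = rng.uniform(size=20)
        a = classify_nutrition_sensitive(dc, dl)
        b = classify_nutrition_sensitive(dc.iloc[::-1], dl.sample(frac=1, random_state=0))
        pd.testing.assert_frame_equal(a, b)


class TestFisher:
    def test_published_buccal_table(self):
        _, p = reference_overlap_fisher(162, 10, 1723, 238)
        assert round(p, 3) == 0.005

    def test_published_aries_table(self):
        _, p = reference_overlap_fisher(162, 9, 1723, 200)
        assert round(p, 3) == 0.018

    def test_symmetric_table_p_one(self):
        _, p = reference_overlap_fisher(10, 5, 10, 5)
        assert p == 1.0

    def test_matches_hypergeometric_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n_s = int(rng.integers(5, 60))
            n_i = int(rng.integers(5, 60))
            k_s = int(rng.integers(0, n_s + 1))
            k_i = int(rng.integers(0, n_i + 1))
            _, p = reference_overlap_fisher(n_s, k_s, n_i, k_i)
            # enumerate all tables with the same margins
            K = k_s + k_i
            N = n_s + n_i
            pmf_obs = stats.hypergeom.pmf(k_s, N, K, n_s)
            ks = np.arange(max(0, K - n_i), min(K, n_s) + 1)
            pmf = stats.hypergeom.pmf(ks, N, K, n_s)
            brute = pmf[pmf <= pmf_obs * (1 + 1e-9)].sum()
            assert p == pytest.approx(min(1.0, brute), rel=1e-6)

    def test_doubling_alternative(self):
        _, p_dbl = reference_overlap_fisher(162, 10, 1723, 238, method="doubling")
        assert 0 < p_dbl <= 1
        # doubling equals twice the smaller one-sided hypergeometric tail
        less = stats.hypergeom.cdf(10, 162 + 1723, 10 + 238, 162)
        greater = stats.hypergeom.sf(9, 162 + 1723, 10 + 238, 162)
        assert p_dbl == pytest.approx(min(1.0, 2 * min(less, greater)), rel=1e-9)
        _, p_sym = reference_overlap_fisher(10, 5, 10, 5, method="doubling")
        assert p_sym == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            reference_overlap_fisher(5, 6, 10, 2)
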