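"""QTL mapping: MAF, cis windows, OLS association, psQTL LRT, BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cistrio import (
    CohortConfig,
    GeneInterval,
    GenotypeMatrix,
    bh_threshold,
    best_pqtl_per_gene,
    compute_maf,
    fit_linear_assoc,
    lrt_psqtl,
    map_all_qtls,
    select_cis_candidates,
    simulate_cohort,
)
from cistrio.exceptions import DegenerateDataError, ParameterError


class TestComputeMaf:
    @pytest.mark.parametrize(
        "dosages,expected",
        [
            ([0, 0, 1, 1, 2], 0.4),
            ([0, 0, 0, 0], 0.0),
            ([2, 2, 2, 2], 0.0),  # folded to the minor side
            ([0, 1, np.nan, 2], 3 / 6),
        ],
    )
    def test_examples(self, dosages, expected):
        assert compute_maf(np.array(dosages, dtype=float)) == pytest.approx(expected)

    def test_all_missing(self):
        with pytest.raises(DegenerateDataError):
            compute_maf(np.array([np.nan, np.nan]))


def _geno(positions, dosage_rows, chrom="chr1"):
    ids = [f"v{i}" for i in range(len(positions))]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index(ids, name="variant_id"),
    )
    samples = [f"s{i}" for i in range(len(dosage_rows[0]))]
    dosages = pd.DataFrame(dosage_rows, index=variants.index, columns=samples)
    return GenotypeMatrix(variants=variants, dosages=dosages)


class TestSelectCisCandidates:
    gene = GeneInterval("g", "chr1", 100_000, 105_000)

    def test_window_boundaries_inclusive(self):
        common = [0.0, 1.0, 2.0, 1.0, 0.0, 1.0]
        geno = _geno([80_000, 79_999, 102_000, 125_000, 125_001],
                     [common] * 5)
        ids = select_cis_candidates(self.gene, geno)
        assert ids == ["v0", "v2", "v3"]

    def test_maf_strictly_greater(self):
        # 10 samples: one het -> MAF exactly 0.05; two het -> 0.10; three -> 0.15
        rows = [
            [1] + [0] * 9,
            [1, 1] + [0] * 8,
            [1, 1, 1] + [0] * 7,
        ]
        geno = _geno([101_000, 102_000, 103_000], [[float(x) for x in r] for r in rows])
        ids = select_cis_candidates(self.gene, geno, maf_min=0.10)
        assert ids == ["v2"]  # exactly 0.10 is excluded

    def test_other_chromosome_excluded(self):
        geno = _geno([101_000], [[0.0, 1.0, 2.0, 1.0]], chrom="chr2")
        assert select_cis_candidates(self.gene, geno) == []


class TestFitLinearAssoc:
    def test_normal_equations_oracle(self):
        dose = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        trait = 2 * dose + np.array([0.1, -0.1, 0.05, -0.05, 0.0, 0.0])
        res = fit_linear_assoc(trait, dose)
        # closed-form OLS slope from the normal equations
        x = np.column_stack([np.ones(6), dose])
        beta = np.linalg.solve(x.T @ x, x.T @ trait)
        assert res.effect == pytest.approx(beta[1], abs=1e-12)
        assert res.n_used == 6

    def test_matches_f_test(self, rng):
        dose = rng.binomial(2, 0.4, size=30).astype(float)
        trait = 0.3 * dose + rng.normal(size=30)
        res = fit_linear_assoc(trait, dose)
        # single-regressor t-test p equals the model F-test p
        f_p = stats.f.sf(res.stat**2, 1, 28)
        assert res.p_value == pytest.approx(f_p, rel=1e-9)

    def test_null_p_uniform(self, rng):
        pvals = []
        dose = rng.binomial(2, 0.3, size=62).astype(float)
        for _ in range(2000):
            trait = rng.normal(size=62)
            pvals.append(fit_linear_assoc(trait, dose).p_value)
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.05

    def test_constant_trait_convention(self):
        res = fit_linear_assoc(np.ones(6), np.array([0, 1, 2, 0, 1, 2], dtype=float))
        assert res.effect == 0.0 and res.p_value == 1.0

    def test_constant_dosage_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_linear_assoc(np.arange(6.0), np.ones(6))


class TestLrtPsqtl:
    def test_nested_equality_gives_zero(self):
        rng = np.random.default_rng(0)
        mrna = rng.normal(size=12)
        dose = rng.binomial(2, 0.4, size=12).astype(float)
        protein = 2.0 + 3.0 * mrna  # exactly the reduced model
        res = lrt_psqtl(protein, mrna, dose)
        assert res.stat == 0.0 and res.p_value == 1.0

    def test_rss_oracle_n8(self):
        dose = np.array([0, 1, 2, 0, 1, 2, 1, 0], dtype=float)
        mrna = np.array([0.2, -0.3, 0.5, 0.1, 0.9, -0.2, 0.4, -0.6])
        protein = np.array([0.5, 0.1, 1.2, -0.3, 0.8, 0.6, -0.1, 0.2])
        res = lrt_psqtl(protein, mrna, dose)

        def rss(design):
            beta = np.linalg.solve(design.T @ design, design.T @ protein)
            r = protein - design @ beta
            return r @ r

        ones = np.ones(8)
        rss_full = rss(np.column_stack([ones, dose, mrna]))
        rss_red = rss(np.column_stack([ones, mrna]))
        assert res.stat == pytest.approx(8 * np.log(rss_red / rss_full), rel=1e-10)
        assert res.p_value == pytest.approx(stats.chi2.sf(res.stat, 1), rel=1e-12)

    def test_power_under_direct_effect(self, rng):
        # protein has a genotype effect beyond mRNA: high rejection rate
        hits = 0
        reps = 300
        for _ in range(reps):
            dose = rng.binomial(2, 0.3, size=62).astype(float)
            mrna = rng.normal(scale=0.5, size=62)
            protein = 0.8 * dose + mrna + rng.normal(scale=0.5, size=62)
            hits += lrt_psqtl(protein, mrna, dose).p_value < 0.05
        assert hits / reps > 0.5

    def test_collinear_inputs_rejected(self):
        dose = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        with pytest.raises(DegenerateDataError):
            lrt_psqtl(np.arange(6.0), 2 * dose + 1, dose)


def _brute_force_bh(p, fdr):
    """Literal step-up definition, re-derived independently."""
    m = len(p)
    ordered = sorted(p)
    cutoff = None
    for i in range(1, m + 1):
        if ordered[i - 1] <= i * fdr / m:
            cutoff = ordered[i - 1]
    if cutoff is None:
        return 0.0, 0
    return cutoff, sum(1 for q in p if q <= cutoff)


class TestBhThreshold:
    def test_worked_example(self):
        res = bh_threshold(np.array([0.001, 0.02, 0.03, 0.5]), fdr=0.1)
        assert res.p_cutoff == pytest.approx(0.03)
        assert res.n_discoveries == 3

    def test_all_ones(self):
        res = bh_threshold(np.ones(5), fdr=0.1)
        assert res.n_discoveries == 0 and res.p_cutoff == 0.0

    def test_single_value(self):
        assert bh_threshold(np.array([0.05]), fdr=0.1).n_discoveries == 1
        assert bh_threshold(np.array([0.15]), fdr=0.1).n_discoveries == 0

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            bh_threshold(np.array([]))

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40),
        st.sampled_from([0.05, 0.1, 0.2]),
    )
    def test_matches_brute_force(self, pvals, fdr):
        res = bh_threshold(np.array(pvals), fdr=fdr)
        cutoff, n_disc = _brute_force_bh(pvals, fdr)
        assert res.p_cutoff == pytest.approx(cutoff)
        assert res.n_discoveries == n_disc


@pytest.fixture(scope="module")
def strong_cohort():
    return simulate_cohort(CohortConfig(n_individuals=120), seed=21)


class TestMapAllQtls:
    def test_generative_construction_detected(self, strong_cohort):
        c = strong_cohort
        records, _ = map_all_qtls(c.genotypes, c.mrna, c.protein, c.genes)
        sig = records[records["significant"]]

        def causal_sig(gene_id, qtl_type):
            vid = c.truth.loc[gene_id, "causal_variant_id"]
            return (
                (sig["gene_id"] == gene_id)
                & (sig["variant_id"] == vid)
                & (sig["qtl_type"] == qtl_type)
            ).any()

        for gid, row in c.truth.iterrows():
            if row.true_pattern in (1, 3, 4, 6):  # S -> R edge
                assert causal_sig(gid, "eQTL"), f"{gid} missing eQTL"
            if row.true_pattern in (2, 3, 5, 6):  # direct S -> N edge
                assert causal_sig(gid, "pQTL"), f"{gid} missing pQTL"

    def test_deterministic(self, strong_cohort):
        c = strong_cohort
        r1, _ = map_all_qtls(c.genotypes, c.mrna, c.protein, c.genes)
        r2, _ = map_all_qtls(c.genotypes, c.mrna, c.protein, c.genes)
        pd.testing.assert_frame_equal(r1, r2)

    def test_no_shared_samples(self, strong_cohort):
        c = strong_cohort
        renamed = c.mrna.values.rename(columns=lambda s: s + "_x")
        from cistrio import ExpressionMatrix

        with pytest.raises(ParameterError):
            map_all_qtls(
                c.genotypes, ExpressionMatrix(renamed), c.protein, c.genes
            )

    def test_null_cohort_fdr_controlled(self):
        null = simulate_cohort(
            CohortConfig(
                genes_per_pattern={1: 40}, effect=0.0, n_decoys=2,
            ),
            seed=5,
        )
        records, fdr_res = map_all_qtls(
            null.genotypes, null.mrna, null.protein, null.genes
        )
        # every test is null: discovery proportion stays near the FDR level
        frac = records["significant"].mean()
        assert frac <= 0.12


class TestBestPqtlPerGene:
    def _records(self, rows):
        return pd.DataFrame(
            rows,
            columns=["qtl_type", "gene_id", "variant_id", "chrom", "pos",
                     "effect", "se", "stat", "p_value", "n_used"],
        )

    def test_min_p_regardless_of_significance(self):
        recs = self._records(
            [
                ("pQTL", "g", "a", "chr1", 100, 0, 0, 0, 0.2, 60),
                ("pQTL", "g", "b", "chr1", 200, 0, 0, 0, 0.04, 60),
                ("pQTL", "g", "c", "chr1", 300, 0, 0, 0, 0.9, 60),
            ]
        )
        genes = [GeneInterval("g", "chr1", 150, 250)]
        best = best_pqtl_per_gene(recs, genes)
        assert best["variant_id"].tolist() == ["b"]

    def test_tie_breaks_to_midpoint_then_coordinate(self):
        genes = [GeneInterval("g", "chr1", 1000, 2000)]  # midpoint 1500
        recs = self._records(
            [
                ("pQTL", "g", "far", "chr1", 100, 0, 0, 0, 0.05, 60),
                ("pQTL", "g", "near", "chr1", 1400, 0, 0, 0, 0.05, 60),
                ("pQTL", "g", "near2", "chr1", 1600, 0, 0, 0, 0.05, 60),
            ]
        )
        best = best_pqtl_per_gene(recs, genes)
        # 1400 and 1600 are equidistant from 1500; smaller coordinate wins
        assert best["variant_id"].tolist() == ["near"]

    def test_no_pqtl_rows(self):
        recs = self._records([("eQTL", "g", "a", "chr1", 1, 0, 0, 0, 0.5, 60)])
        with pytest.raises(ParameterError):
            best_pqtl_per_gene(recs, [GeneInterval("g", "chr1", 1, 10)])
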