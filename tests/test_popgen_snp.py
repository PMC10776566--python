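"""QC filtering, diversity, HWE/LD exact tests, F_ST, Mantel and outlier scan."""

import numpy as np
import pandas as pd
import pytest

from seaconnect.fixtures import FixtureConfig, make_genotypes
from seaconnect.popgen_snp import (
    GenotypeDataset,
    PairwiseMatrix,
    diversity,
    exclude_failed_samples,
    filter_loci,
    fisher_exact_rxc,
    fst_pairwise_matrix,
    fst_standardised,
    fst_wc,
    geographic_distance_matrix,
    hwe_exact,
    hwe_exact_pvalue,
    ibd_mantel,
    ld_pairwise,
    outlier_scan,
    standardised_fst_transect,
)


def _gd(dosage, localities=None, ids=None, loci=None, meta=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    return GenotypeDataset(
        ind_ids=ids or [f"i{k}" for k in range(n)],
        localities=np.array(localities if localities is not None else ["pop1"] * n, dtype=object),
        locus_ids=loci or [f"l{j}" for j in range(m)],
        dosage=dosage,
        locus_meta=meta,
    )


class TestFiltering:
    def test_low_call_rate_locus_removed(self):
        dosage = np.zeros((100, 2), dtype=np.int8)
        dosage[:, 1] = np.where(np.arange(100) % 2 == 0, 1, 0)  # keep polymorphic
        dosage[:10, 0] = -1
        dosage[10:60, 0] = 1
        gd = _gd(dosage)
        out, counts = filter_loci(gd, min_call_rate=0.95, min_maf=0.0)
        assert counts["call_rate"] == 1
        assert out.locus_ids == ["l1"]

    def test_low_maf_locus_removed(self):
        dosage = np.zeros((100, 2), dtype=np.int8)
        dosage[:4, 0] = 1  # MAF 0.02
        dosage[:50, 1] = 1  # MAF 0.25
        out, counts = filter_loci(_gd(dosage), min_call_rate=0.0, min_maf=0.05)
        assert counts["maf"] == 1
        assert out.locus_ids == ["l1"]

    def test_constructed_panel_counts(self):
        """10 loci with 3 constructed failures → 7 retained, per-criterion counts match."""
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(40, 10)).astype(np.int8)
        dosage[:10, 0] = -1  # call rate 0.75
        dosage[:, 1] = 0
        dosage[0, 1] = 1  # MAF 1/80
        meta = pd.DataFrame({"reproducibility": [1.0] * 10}, index=[f"l{j}" for j in range(10)])
        meta.loc["l2", "reproducibility"] = 0.8
        gd = _gd(dosage, meta=meta)
        out, counts = filter_loci(gd, min_call_rate=0.95, min_maf=0.05, min_reproducibility=0.95)
        assert counts == {"call_rate": 1, "maf": 1, "reproducibility": 1, "retained": 7}

    def test_filtering_idempotent(self, two_pop_genotypes):
        once, _ = filter_loci(two_pop_genotypes, 0.95, 0.05)
        twice, counts = filter_loci(once, 0.95, 0.05)
        assert counts["call_rate"] == 0 and counts["maf"] == 0
        assert twice.locus_ids == once.locus_ids

    def test_all_loci_removed_warns(self):
        dosage = np.zeros((10, 2), dtype=np.int8)  # monomorphic: MAF 0
        with pytest.warns(UserWarning, match="all loci removed"):
            out, _ = filter_loci(_gd(dosage), min_call_rate=0.5, min_maf=0.05)
        assert out.n_loci == 0

    def test_sample_exclusion(self):
        dosage = np.ones((5, 4), dtype=np.int8)
        dosage[0, :] = -1  # fully missing individual
        gd = _gd(dosage, localities=["a", "a", "b", "b", "b"])
        out, sizes = exclude_failed_samples(gd, max_missing_per_ind=0.5)
        assert out.n_ind == 4
        assert sizes == {"b": 3, "a": 1}

    def test_no_missing_all_retained(self, two_pop_genotypes):
        out, sizes = exclude_failed_samples(two_pop_genotypes, 0.1)
        assert out.n_ind == two_pop_genotypes.n_ind
        assert sum(sizes.values()) == 60


class TestDiversity:
    def test_monomorphic_locus(self):
        gd = _gd(np.zeros((10, 1), dtype=np.int8))
        d = diversity(gd, rarefaction_g=4)
        assert d.loc["pop1", "Na"] == 1.0
        assert d.loc["pop1", "Ar"] == 1.0
        assert d.loc["pop1", "Ho"] == 0.0
        assert d.loc["pop1", "He"] == 0.0

    def test_all_heterozygous(self):
        gd = _gd(np.ones((10, 1), dtype=np.int8))
        assert diversity(gd, 4).loc["pop1", "Ho"] == 1.0

    def test_rarefaction_matches_exhaustive_subsampling(self):
        """Ar at g=4 equals the mean allele count over all C(N,4) subsamples."""
        from itertools import combinations

        dosage = np.array([[2], [1], [0], [0], [0]], dtype=np.int8)  # alleles: 3 alt, 7 ref
        gd = _gd(dosage)
        g = 4
        alleles = [1, 1, 1] + [0] * 7
        counts = []
        for sub in combinations(range(10), g):
            drawn = {alleles[i] for i in sub}
            counts.append(len(drawn))
        expected = np.mean(counts)
        got = diversity(gd, rarefaction_g=g).loc["pop1", "Ar"]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_he_unbiased_correction(self):
        # 2 individuals, p=0.5 -> raw He=0.5, corrected by 2n/(2n-1)=4/3
        gd = _gd(np.array([[2], [0]], dtype=np.int8))
        assert diversity(gd, 2).loc["pop1", "He"] == pytest.approx(0.5 * 4 / 3)


class TestHWEExact:
    def test_modal_configuration_p_one(self):
        p, _ = hwe_exact_pvalue(25, 50, 25)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_extreme_heterozygote_deficiency(self):
        p, p_def = hwe_exact_pvalue(50, 0, 50)
        assert p < 1e-10 and p_def < 1e-10

    def test_monomorphic_p_one(self):
        p, _ = hwe_exact_pvalue(20, 0, 0)
        assert p == 1.0

    @pytest.mark.parametrize("n", [3, 5, 8, 12, 15])
    def test_matches_allele_shuffle_simulation(self, n):
        """Exact p equals the probability under random pairing of the allele pool."""
        rng = np.random.default_rng(n)
        n_minor = rng.integers(1, n + 1)
        pool = np.array([1] * n_minor + [0] * (2 * n - n_minor))
        n_sim = 40000
        hets = np.zeros(n_sim, dtype=int)
        for s in range(n_sim):
            rng.shuffle(pool)
            g = pool[::2] + pool[1::2]
            hets[s] = np.sum(g == 1)
        # simulate the exact two-sided rule on the empirical distribution
        vals, freq = np.unique(hets, return_counts=True)
        prob = freq / n_sim
        obs_h = vals[np.argmax(prob)]  # test at the modal value and one tail value
        for h_obs in (int(vals[0]), int(obs_h)):
            n_aa = (n_minor - h_obs) // 2
            n_AA = n - n_aa - h_obs
            p_exact, _ = hwe_exact_pvalue(n_AA, h_obs, n_aa)
            p_obs = prob[vals == h_obs][0]
            p_mc = prob[prob <= p_obs * (1 + 1e-9)].sum()
            assert p_exact == pytest.approx(p_mc, abs=0.02)

    def test_full_enumeration_small_samples(self):
        """Conditional het distribution sums to 1 and matches direct enumeration for 2n ≤ 30."""
        from math import comb as C

        for n in range(2, 16):
            for n_minor in range(0, n + 1):
                from seaconnect.popgen_snp import _hwe_het_distribution

                hs, probs = _hwe_het_distribution(n, n_minor)
                assert probs.sum() == pytest.approx(1.0)
                # direct multinomial enumeration oracle
                from math import factorial

                weights = []
                for h in hs:
                    naa = (n_minor - h) // 2
                    nAA = n - naa - h
                    w = factorial(n) / (factorial(nAA) * factorial(h) * factorial(naa)) * 2**h
                    weights.append(w)
                weights = np.array(weights, dtype=float)
                assert np.allclose(probs, weights / weights.sum())

    def test_dataset_level_flags(self):
        # deficient locus: all homozygotes at p=0.5
        dosage = np.array([[0], [0], [0], [0], [2], [2], [2], [2]], dtype=np.int8)
        res = hwe_exact(_gd(dosage))
        assert res.loc[0, "het_deficient"]

    def test_too_few_genotypes_reported_missing(self):
        dosage = np.full((3, 1), -1, dtype=np.int8)
        dosage[0, 0] = 1
        res = hwe_exact(_gd(dosage))
        assert np.isnan(res.loc[0, "p"])


class TestLDExact:
    def test_duplicated_locus_strong_association(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=60).astype(np.int8)
        gd = _gd(np.column_stack([col, col]))
        res = ld_pairwise(gd, pairs=[("l0", "l1")])
        assert res["p"].iloc[0] < 1e-6

    def test_monomorphic_partner_p_one(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, size=40).astype(np.int8)
        b = np.zeros(40, dtype=np.int8)
        gd = _gd(np.column_stack([a, b]))
        res = ld_pairwise(gd, pairs=[("l0", "l1")])
        assert res["p"].iloc[0] == 1.0

    def test_exact_matches_monte_carlo(self):
        """Enumerated p agrees with the seeded Monte Carlo fallback."""
        tab = np.array([[8, 2, 1], [3, 6, 2], [1, 2, 5]])
        p_exact = fisher_exact_rxc(tab)
        p_mc = fisher_exact_rxc(tab, rng=np.random.default_rng(0), max_tables=1, n_mc=20000)
        assert p_exact == pytest.approx(p_mc, abs=0.02)

    def test_2x2_matches_scipy_fisher(self):
        from scipy.stats import fisher_exact

        tab = np.array([[8, 2], [3, 9]])
        assert fisher_exact_rxc(tab) == pytest.approx(fisher_exact(tab)[1], abs=1e-9)

    def test_null_rejection_rate_is_valid(self):
        """Independent loci: rejection rate at α=0.01 does not exceed the binomial
        upper bound (exact conditional tests are valid, possibly conservative)."""
        cfg = FixtureConfig(seed=21, n_pops=1, pop_names=("P",), n_ind_per_pop=(60,),
                            n_loci=120, fst_target=0.0)
        gd = make_genotypes(cfg)
        res = ld_pairwise(gd, max_pairs=1000, seed=3)
        rate = float(np.mean(res["p"] < 0.01))
        upper = 0.01 + 1.96 * np.sqrt(0.01 * 0.99 / len(res))
        assert rate <= upper


class TestWeirCockerham:
    def test_duplicated_population_theta_near_zero(self, two_pop_genotypes):
        gd = two_pop_genotypes
        dup = GenotypeDataset(
            ind_ids=[f"a{k}" for k in range(gd.n_ind)] + [f"b{k}" for k in range(gd.n_ind)],
            localities=np.array(["X"] * gd.n_ind + ["Y"] * gd.n_ind, dtype=object),
            locus_ids=gd.locus_ids,
            dosage=np.vstack([gd.dosage, gd.dosage]),
        )
        theta, _ = fst_wc(dup, "X", "Y", n_perm=0)
        assert abs(theta) < 0.01

    def test_fixed_differences_theta_one(self):
        dosage = np.array([[2] * 5] * 10 + [[0] * 5] * 10, dtype=np.int8)
        gd = _gd(dosage, localities=["A"] * 10 + ["B"] * 10)
        theta, _ = fst_wc(gd, "A", "B", n_perm=0)
        assert theta == pytest.approx(1.0)

    def test_hand_computed_variance_components(self):
        """3-locus toy panel against a spreadsheet-style hand calculation.

        Locus l0: pop1 = 5×(2) + 5×(0), pop2 = 10×(0) → a=0.1111, b=0.1389, c=0.
        Locus l1: monomorphic → excluded.
        Locus l2: pop1 = 10×(1), pop2 = 10×(0)      → a=0.125, b=−0.125, c=0.25.
        Multilocus θ = (0.1111+0.125)/(0.25+0.25) = 0.47222.
        """
        dos = np.zeros((20, 3), dtype=np.int8)
        dos[:5, 0] = 2
        dos[:10, 2] = 1
        gd = _gd(dos, localities=["P1"] * 10 + ["P2"] * 10)
        theta, _ = fst_wc(gd, "P1", "P2", n_perm=0)
        assert theta == pytest.approx(17.0 / 36.0, abs=1e-12)

    def test_allele_label_swap_invariance(self, two_pop_genotypes):
        gd = two_pop_genotypes
        flipped = GenotypeDataset(
            ind_ids=gd.ind_ids,
            localities=gd.localities,
            locus_ids=gd.locus_ids,
            dosage=np.where(gd.dosage == -1, -1, 2 - gd.dosage).astype(np.int8),
        )
        t1, _ = fst_wc(gd, "North", "South", n_perm=0)
        t2, _ = fst_wc(flipped, "North", "South", n_perm=0)
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_permutation_p_significant_when_differentiated(self):
        cfg = FixtureConfig(seed=8, n_pops=2, pop_names=("A", "B"), n_ind_per_pop=(30, 30),
                            n_loci=300, fst_target=0.2)
        gd = make_genotypes(cfg)
        theta, p = fst_wc(gd, "A", "B", n_perm=99, seed=5)
        assert theta > 0.1 and p == pytest.approx(0.01, abs=1e-12)

    def test_requires_two_individuals(self):
        gd = _gd(np.zeros((3, 2), dtype=np.int8), localities=["A", "A", "B"])
        with pytest.raises(ValueError, match="at least 2"):
            fst_wc(gd, "A", "B", n_perm=0)


class TestStandardisedFst:
    def test_zero_theta(self):
        assert fst_standardised(0.0, 0.3) == 0.0

    def test_hs_zero_max_is_one(self):
        assert fst_standardised(0.4, 0.0) == pytest.approx(0.4)

    def test_formula_value(self):
        # theta / [(1-hs)/(1+hs)] = 0.05 * (1+0.3)/(1-0.3)
        assert fst_standardised(0.05, 0.3, k=2) == pytest.approx(0.05 * 1.3 / 0.7)

    def test_hs_one_undefined(self):
        assert np.isnan(fst_standardised(0.1, 1.0))

    def test_transect_ordering(self, two_pop_genotypes):
        fst = fst_pairwise_matrix(two_pop_genotypes, n_perm=0)
        tr = standardised_fst_transect(two_pop_genotypes, fst, {"North": 0.0, "South": 100.0})
        assert list(tr["midpoint"]) == sorted(tr["midpoint"])
        assert (tr["theta_std"] >= tr["theta"] - 1e-12).all()


class TestMantel:
    def _mat(self, values, labels=("a", "b", "c", "d")):
        return PairwiseMatrix(labels=list(labels), values=np.asarray(values, dtype=float))

    def _random_dist(self, rng, n=5):
        m = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        m[iu] = rng.random(len(iu[0]))
        return self._mat(m + m.T, labels=[str(i) for i in range(n)])

    def test_identical_matrices_r_one(self):
        rng = np.random.default_rng(0)
        m = self._random_dist(rng)
        r, p = ibd_mantel(m, m, n_perm=199, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200, abs=0.03)

    def test_anticorrelated_r_minus_one(self):
        rng = np.random.default_rng(1)
        m = self._random_dist(rng)
        neg = self._mat(np.where(m.values > 0, 2.0 - m.values, 0.0), labels=m.labels)
        r, _ = ibd_mantel(m, neg, n_perm=99, seed=1)
        assert r == pytest.approx(-1.0)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(2)
        a, b = self._random_dist(rng), self._random_dist(rng)
        r1, _ = ibd_mantel(a, b, n_perm=0, seed=0)
        perm = np.array([3, 1, 4, 0, 2])
        a2 = self._mat(a.values[np.ix_(perm, perm)], labels=[a.labels[i] for i in perm])
        b2 = self._mat(b.values[np.ix_(perm, perm)], labels=[b.labels[i] for i in perm])
        r2, _ = ibd_mantel(a2, b2, n_perm=0, seed=0)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_cross_check_against_skbio(self):
        from skbio.stats.distance import mantel as skbio_mantel
        from skbio import DistanceMatrix

        rng = np.random.default_rng(3)
        a, b = self._random_dist(rng, 6), self._random_dist(rng, 6)
        r, _ = ibd_mantel(a, b, n_perm=0, seed=0)
        r_ref, _, _ = skbio_mantel(DistanceMatrix(a.values), DistanceMatrix(b.values), permutations=0)
        assert r == pytest.approx(r_ref, abs=1e-12)

    def test_too_few_localities(self):
        m = self._mat(np.zeros((2, 2)), labels=["a", "b"])
        with pytest.raises(ValueError, match="at least 3"):
            ibd_mantel(m, m)

    def test_geographic_distance_conventions(self):
        coords = pd.DataFrame({"locality": ["a", "b"], "lon": [0.0, 1.0], "lat": [0.0, 0.0]})
        eu = geographic_distance_matrix(coords, "euclidean")
        gc = geographic_distance_matrix(coords, "great_circle")
        assert eu.values[0, 1] == pytest.approx(111.19, abs=0.1)
        assert gc.values[0, 1] == pytest.approx(111.19, abs=0.1)


class TestOutlierScan:
    def test_single_locality_rejected(self):
        gd = _gd(np.zeros((5, 3), dtype=np.int8))
        with pytest.raises(ValueError, match="at least 2"):
            outlier_scan(gd)

    def test_spiked_locus_attains_minimal_p(self):
        """A fixed-difference locus among a weakly structured background is flagged."""
        cfg = FixtureConfig(seed=13, n_pops=2, pop_names=("A", "B"), n_ind_per_pop=(30, 30),
                            n_loci=200, fst_target=0.02)
        gd = make_genotypes(cfg)
        gd.dosage[:30, 0] = 2
        gd.dosage[30:, 0] = 0
        res = outlier_scan(gd, n_perm=499, seed=4)
        assert res["theta_locus"].iloc[0] == pytest.approx(1.0)
        assert res["p"].iloc[0] == res["p"].min()
        assert res["p"].iloc[0] < 0.01
        assert res["q"].iloc[0] == res["q"].min()

    def test_null_rejection_rate_calibrated(self):
        """Panmictic data: fraction of loci with p ≤ 0.05 within the binomial CI."""
        cfg = FixtureConfig(seed=17, n_pops=3, pop_names=("A", "B", "C"),
                            n_ind_per_pop=(25, 25, 25), n_loci=1000, fst_target=0.0)
        gd = make_genotypes(cfg)
        res = outlier_scan(gd, n_perm=999, seed=9)
        rate = float(np.mean(res["p"].dropna() <= 0.05))
        n = res["p"].notna().sum()
        half = 1.96 * np.sqrt(0.05 * 0.95 / n)
        assert 0.05 - half <= rate <= 0.05 + half


class TestGenotypeIO:
    def test_tsv_round_trip(self, two_pop_genotypes, tmp_path):
        p = tmp_path / "g.tsv"
        two_pop_genotypes.to_tsv(p)
        back = GenotypeDataset.from_tsv(p)
        assert np.array_equal(back.dosage, two_pop_genotypes.dosage)
        assert list(back.localities) == list(two_pop_genotypes.localities)

    def test_vcf_round_trip(self, two_pop_genotypes, tmp_path):
        p = tmp_path / "g.vcf"
        two_pop_genotypes.to_vcf(p)
        back = GenotypeDataset.from_vcf(p)
        assert np.array_equal(back.dosage, two_pop_genotypes.dosage)
        assert list(back.localities) == list(two_pop_genotypes.localities)

    def test_vcf_read_cross_checked_with_cyvcf2(self, two_pop_genotypes, tmp_path):
        cyvcf2 = pytest.importorskip("cyvcf2")
        p = tmp_path / "g.vcf"
        two_pop_genotypes.to_vcf(str(p))
        ours = GenotypeDataset.from_vcf(p)
        vcf = cyvcf2.VCF(str(p), gts012=True)
        ref = np.array([v.gt_types.copy() for v in vcf]).T
        ref = np.where(ref == 3, -1, ref)
        assert np.array_equal(ours.dosage, ref.astype(np.int8))
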