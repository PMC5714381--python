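"""Peak-gene association, hypergeometric feature bias, bootstrap enrichment."""

import numpy as np
import pytest
from scipy import stats

import peaklink as pl
from peaklink.geneset_enrichment import EnrichmentError, SkewNormalFitError

from .oracles import hypergeom_enumerate


class TestAssociation:
    def test_counts_per_assigned_gene(self, small_genome):
        ann, _ = small_genome
        peaks, truth = pl.generate_peaks(ann, pl.PeakSimParams(n_peaks=300, seed=1))
        annotated = pl.classify_peaks(peaks.peaks, ann)
        assoc = pl.associate_peaks(annotated, ann)
        assert assoc.total_peaks == 300
        assert assoc.n_genes == len(ann)
        # genes without peaks are implicitly zero
        assert assoc.count_vector().sum() == 300

    def test_missing_gene_assignment_errors(self, toy_annotation, peak_factory):
        bad = pl.AnnotatedPeak(
            peak=peak_factory("chr1", 0, 100, 50), feature="Promoter",
            gene_id="", dist_to_tss=0,
        )
        with pytest.raises(EnrichmentError, match="classif"):
            pl.associate_peaks([bad], toy_annotation)

    def test_poisson_total(self, assoc_factory):
        """Poisson(2) peaks per gene over 500 genes total within 3 SD of 1000."""
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(500)]
        counts = dict(zip(genes, rng.poisson(2.0, size=500)))
        assoc = assoc_factory(genes, counts)
        assert abs(assoc.total_peaks - 1000) < 3 * np.sqrt(1000)


class TestHypergeomFeatureTest:
    def _dist(self, counts):
        return pl.FeatureDistribution(counts=counts, total=sum(counts.values()))

    @pytest.mark.parametrize("k, want_enrich", [(4, 6 / 252), (2, 186 / 252)])
    def test_enumerated_examples(self, k, want_enrich):
        """N_pop=10, K=4, n=5 cases checked against full enumeration of
        all C(10,5)=252 draws."""
        sd = self._dist({"Intron": k, "Promoter": 5 - k})
        bg = self._dist({"Intron": 4, "Promoter": 6})
        r = pl.hypergeom_feature_test(sd, bg, "Intron")
        assert r.p_enrich == pytest.approx(want_enrich, abs=1e-12)
        e, d = hypergeom_enumerate(10, 4, 5, k)
        assert r.p_enrich == pytest.approx(e, abs=1e-12)
        assert r.p_deplete == pytest.approx(d, abs=1e-12)

    def test_certain_feature_gives_p_one(self):
        sd = self._dist({"Exon": 3})
        bg = self._dist({"Exon": 8})
        r = pl.hypergeom_feature_test(sd, bg, "Exon")
        assert r.p_enrich == pytest.approx(1.0)

    def test_exhaustive_oracle_equivalence_small_populations(self):
        """p_enrich and p_deplete match enumeration to 1e-12 for every
        (N_pop <= 12, K, n, k)."""
        for N_pop in range(1, 13):
            for K in range(0, N_pop + 1):
                for n in range(1, N_pop + 1):
                    lo, hi = max(0, n - (N_pop - K)), min(n, K)
                    for k in range(lo, hi + 1):
                        sd = self._dist({"Intron": k, "Exon": n - k})
                        bg = self._dist({"Intron": K, "Exon": N_pop - K})
                        r = pl.hypergeom_feature_test(sd, bg, "Intron")
                        e, d = hypergeom_enumerate(N_pop, K, n, k)
                        assert r.p_enrich == pytest.approx(e, abs=1e-12)
                        assert r.p_deplete == pytest.approx(d, abs=1e-12)
                        assert r.p_enrich + r.p_deplete >= 1.0 - 1e-12

    def test_set_not_subset_rejected(self):
        sd = self._dist({"Intron": 5})
        bg = self._dist({"Intron": 3, "Exon": 10})
        with pytest.raises(EnrichmentError, match="subset"):
            pl.hypergeom_feature_test(sd, bg, "Intron")


class TestBootstrapNull:
    def test_constant_counts_zero_variance(self, assoc_factory):
        genes = [f"g{i}" for i in range(20)]
        assoc = assoc_factory(genes, {g: 2 for g in genes})
        null = pl.bootstrap_null(assoc, set_size=5, B=50, seed=1)
        assert np.all(null == 10)

    def test_full_universe_draw(self, assoc_factory):
        genes = [f"g{i}" for i in range(10)]
        counts = {g: i for i, g in enumerate(genes)}
        assoc = assoc_factory(genes, counts)
        null = pl.bootstrap_null(assoc, set_size=10, B=20, seed=1)
        assert np.all(null == sum(counts.values()))

    def test_pair_enumeration_mean(self, assoc_factory):
        """3 genes with counts {0,1,2}, N=2: each unordered pair equally
        likely so sums 1,2,3 have probability 1/3 each; mean 2."""
        assoc = assoc_factory(["a", "b", "c"], {"a": 0, "b": 1, "c": 2})
        null = pl.bootstrap_null(assoc, set_size=2, B=30000, seed=3)
        assert set(np.unique(null)) == {1, 2, 3}
        se = np.sqrt((2 / 3) / 30000)  # var of sums is 2/3
        assert abs(null.mean() - 2.0) < 3 * se

    def test_seed_reproducible_and_size_checked(self, assoc_factory):
        genes = [f"g{i}" for i in range(50)]
        assoc = assoc_factory(genes, {g: i % 3 for i, g in enumerate(genes)})
        a = pl.bootstrap_null(assoc, 10, B=700, seed=9)
        b = pl.bootstrap_null(assoc, 10, B=700, seed=9)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(EnrichmentError, match="universe"):
            pl.bootstrap_null(assoc, 51, B=10, seed=0)


class TestSkewNormalFit:
    def test_known_skewed_generator_recovered(self):
        """Fit to skew-normal(alpha=5) draws recovers strong positive skew
        and beats the best symmetric-normal fit in log-likelihood."""
        x = stats.skewnorm.rvs(5, size=10000, random_state=21)
        f = pl.fit_skew_normal(x)
        assert f.alpha > 2
        normal_ll = stats.norm.logpdf(x, x.mean(), x.std()).sum()
        assert f.loglik > normal_ll

    def test_matches_reference_fitter(self):
        """Our MLE agrees with scipy's independent skewnorm.fit optimum."""
        x = stats.skewnorm.rvs(3, loc=10, scale=4, size=5000, random_state=5)
        ours = pl.fit_skew_normal(x)
        a, loc, scale = stats.skewnorm.fit(x)
        ref_ll = stats.skewnorm.logpdf(x, a, loc, scale).sum()
        assert ours.loglik >= ref_ll - 0.01
        assert ours.xi == pytest.approx(loc, abs=0.3)
        assert ours.omega == pytest.approx(scale, rel=0.1)

    def test_fitted_distribution_recovers_normal(self):
        """On N(0,1) draws the fitted *distribution* is standard normal:
        centered mean/sd and the 95th-percentile tail are recovered even
        though the direct shape parameter is weakly identified."""
        x = np.random.default_rng(2).standard_normal(10000)
        f = pl.fit_skew_normal(x)
        d = f.alpha / np.sqrt(1 + f.alpha**2)
        mean = f.xi + f.omega * d * np.sqrt(2 / np.pi)
        sd = f.omega * np.sqrt(1 - 2 * d * d / np.pi)
        assert mean == pytest.approx(0.0, abs=0.1)
        assert sd == pytest.approx(1.0, abs=0.05)
        tail = stats.skewnorm.sf(np.quantile(x, 0.95), f.alpha, f.xi, f.omega)
        assert tail == pytest.approx(0.05, abs=0.01)

    def test_constant_samples_degenerate(self):
        f = pl.fit_skew_normal([3.0] * 100)
        assert f.degenerate

    def test_too_few_samples_rejected(self):
        with pytest.raises(EnrichmentError, match="10"):
            pl.fit_skew_normal([1.0, 2.0, 3.0])

    def test_nonconvergence_carries_fallback(self):
        x = stats.skewnorm.rvs(4, size=200, random_state=1)
        with pytest.raises(SkewNormalFitError) as exc:
            pl.fit_skew_normal(x, maxiter=2)
        xi, omega, alpha = exc.value.fallback
        assert omega > 0


class TestBootstrapP:
    def test_median_of_symmetric_null_near_half(self):
        rng = np.random.default_rng(4)
        null = rng.normal(100, 10, size=20000)
        f = pl.fit_skew_normal(null)
        r = pl.bootstrap_p(int(np.median(null)), f, null)
        assert r.p_high == pytest.approx(0.5, abs=0.05)
        assert r.p_low == pytest.approx(0.5, abs=0.05)

    def test_addone_bound_when_observed_above_all(self):
        null = np.zeros(10000, dtype=int)
        r = pl.bootstrap_p(5, None, null)
        assert r.p_high_emp == pytest.approx(1 / 10001)
        assert r.p_low_emp == 1.0

    def test_normal_tail_oracle(self):
        """Null ~ Normal(100,10): observed at the normal 95% point gives
        fitted p_high within 0.01 of 0.05."""
        rng = np.random.default_rng(6)
        null = rng.normal(100, 10, size=10000)
        f = pl.fit_skew_normal(null)
        r = pl.bootstrap_p(116.45, f, null)
        assert r.p_high == pytest.approx(0.05, abs=0.01)

    def test_fitted_and_empirical_tails_agree(self, small_genome):
        """For a real association null with B=5000 the fitted tail matches
        the empirical tail within 0.02 at several quantiles."""
        ann, _ = small_genome
        peaks, _ = pl.generate_peaks(ann, pl.PeakSimParams(n_peaks=800, seed=14))
        assoc = pl.associate_peaks(pl.classify_peaks(peaks.peaks, ann), ann)
        null = pl.bootstrap_null(assoc, set_size=8, B=5000, seed=15)
        f = pl.fit_skew_normal(null)
        # evaluate between lattice atoms so both routes measure the same mass
        for q in (0.05, 0.25, 0.5, 0.75, 0.95):
            x = float(np.quantile(null, q)) + 0.5
            fitted = stats.skewnorm.sf(x, f.alpha, loc=f.xi, scale=f.omega)
            assert abs(fitted - np.mean(null > x)) < 0.02, q

    def test_end_to_end_reproducible(self, small_genome):
        ann, _ = small_genome
        peaks, _ = pl.generate_peaks(ann, pl.PeakSimParams(n_peaks=400, seed=2))
        assoc = pl.associate_peaks(pl.classify_peaks(peaks.peaks, ann), ann)
        gs = pl.GeneSet("s", tuple(ann.gene_ids[:6]))
        r1 = pl.bootstrap_enrichment_test(assoc, gs, B=500, seed=77)
        r2 = pl.bootstrap_enrichment_test(assoc, gs, B=500, seed=77)
        assert r1.observed == r2.observed
        np.testing.assert_array_equal(r1.null_counts, r2.null_counts)
        assert (r1.p_high, r1.p_low) == (r2.p_high, r2.p_low)
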