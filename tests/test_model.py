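import math

import numpy as np
import pytest
from scipy import stats

from bidipol import (
    GammaFamily,
    GammaHyperprior,
    Hyperparams,
    PairParams,
    PairPromoterModel,
    RegulatoryRegion,
    SinglePromoterModel,
    SinglePromoterParams,
    classify_promoters,
    expected_lambda_pair,
    expected_lambda_single,
    extract_regulatory_region,
    fit_hyperparams,
    fit_pair_map,
    fit_single_promoter,
    log_likelihood,
    log_prior,
    pair_geometry,
    simulate_single_profile,
)
from bidipol.profiles import MID, NEG, POS


def _params(B=2, T=6, S=50, Kp=200, Kt=300):
    return SinglePromoterParams(B=B, T=T, S=S, Kp=Kp, Kt=Kt)


def _pair(g1=None, g2=None):
    return PairParams(gene1=g1 or _params(), gene2=g2 or _params())


class TestExpectedLambda:
    def test_tss_bin_gives_S(self):
        assert expected_lambda_single(_params(), 0.0, "promoter") == pytest.approx(50)

    def test_half_life_distance(self):
        # at D = Kp ln 2 the excess has halved: 2 + 48/2 = 26
        d = 200 * math.log(2)
        assert expected_lambda_single(_params(), d, "promoter") == pytest.approx(26)

    def test_far_limit_is_background(self):
        assert expected_lambda_single(_params(), 1e9, "promoter") == pytest.approx(2)

    def test_nonpositive_decay_scale_rejected(self):
        with pytest.raises(ValueError):
            SinglePromoterParams(B=2, T=6, S=50, Kp=-1, Kt=300)

    def test_mid_bin_at_both_tss_gives_S1_plus_S2(self):
        Y = _pair(_params(S=50), _params(S=70))
        assert expected_lambda_pair(Y, MID, 0.0, 0.0) == pytest.approx(120)

    def test_neg_branch_is_promoter1_plus_transcript2(self):
        Y = _pair()
        d1, d2 = 400.0, 120.0
        expected = (expected_lambda_single(Y.gene1, d1, "promoter")
                    + expected_lambda_single(Y.gene2, d2, "transcript"))
        assert expected_lambda_pair(Y, NEG, d1, d2) == pytest.approx(expected)

    def test_symmetric_pair_is_swap_invariant_at_midpoint(self):
        Y = _pair()
        assert expected_lambda_pair(Y, MID, 300.0, 300.0) == \
            expected_lambda_pair(Y.swapped(), MID, 300.0, 300.0)

    def test_unknown_region_label(self):
        with pytest.raises(ValueError):
            expected_lambda_pair(_pair(), "XXX", 0.0, 0.0)


class TestLogLikelihood:
    def test_all_zero_counts_unit_lambda(self):
        # 10 bins with lambda = 1 and X = 0: log L = -10
        geom = pair_geometry(distance=40, flank=40, bin_size=20)
        Y = _pair(_params(B=0.5, T=0.5, S=0.5, Kp=200, Kt=300),
                  _params(B=0.5, T=0.5, S=0.5, Kp=200, Kt=300))
        # flat curves: every lambda = 0.5 + 0.5 = 1
        ll = log_likelihood(geom, Y)
        assert ll == pytest.approx(-geom.n_bins)

    def test_single_bin_closed_form(self):
        geom = pair_geometry(distance=0, flank=20, bin_size=20)
        Y = _pair(_params(B=1.5, T=1.5, S=1.5, Kp=100, Kt=100),
                  _params(B=1.5, T=1.5, S=1.5, Kp=100, Kt=100))
        prof = geom.with_counts(np.array([2, 2, 2]))
        # lambda = 3 everywhere, X = 2: per-bin 2 ln 3 - 3 - ln 2
        expected = 3 * (2 * math.log(3) - 3 - math.log(2))
        assert log_likelihood(prof, Y) == pytest.approx(expected, abs=1e-10)

    def test_matches_scalar_poisson_oracle(self, rng):
        geom = pair_geometry(distance=200, flank=400, bin_size=20)
        Y = _pair()
        from bidipol import pair_lambda_profile

        lam = pair_lambda_profile(Y, geom)
        counts = rng.poisson(lam)
        prof = geom.with_counts(counts)
        ll = log_likelihood(prof, Y, transcript_bins=None)
        oracle = sum(
            stats.poisson.logpmf(int(x), mu) for x, mu in zip(counts, lam)
        )
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_transcript_truncation_drops_far_bins(self):
        geom = pair_geometry(distance=200, flank=2000, bin_size=20)
        Y = _pair()
        full = log_likelihood(geom.with_counts(np.zeros(geom.n_bins)), Y,
                              transcript_bins=None)
        trunc = log_likelihood(geom.with_counts(np.zeros(geom.n_bins)), Y,
                               transcript_bins=50)
        assert trunc > full  # fewer (negative) terms

    def test_negative_count_rejected(self):
        geom = pair_geometry(distance=40, flank=40, bin_size=20)
        with pytest.raises(ValueError):
            geom.with_counts(np.full(geom.n_bins, -1))


class TestLogPrior:
    def test_unit_exponential_case(self):
        # alpha = beta = 1 for every family: log prior = -(sum of parameters)
        theta = Hyperparams(**{n: GammaFamily(1.0, 1.0)
                               for n in ("B", "T", "S", "Kp", "Kt")})
        Y = _pair()
        assert log_prior(Y, theta) == pytest.approx(-Y.as_array().sum())

    def test_matches_scipy_gamma_oracle(self, theta):
        Y = _pair(_params(3, 5, 90, 150, 420), _params(1.2, 7, 60, 260, 380))
        oracle = 0.0
        for name in ("B", "T", "S", "Kp", "Kt"):
            fam = theta.family(name)
            for g in (Y.gene1, Y.gene2):
                oracle += stats.gamma.logpdf(getattr(g, name), a=fam.alpha,
                                             scale=fam.beta)
        assert log_prior(Y, theta) == pytest.approx(oracle, abs=1e-10)

    def test_swap_invariant(self, theta):
        Y = _pair(_params(S=90), _params(S=40))
        assert log_prior(Y, theta) == pytest.approx(log_prior(Y.swapped(), theta))


class TestSinglePromoterFit:
    def test_noise_free_recovery(self):
        truth = _params(B=3, T=8, S=100, Kp=150, Kt=400)
        prof = simulate_single_profile(truth, rng=0, noise=False)
        fit = fit_single_promoter(prof)
        assert fit.S == pytest.approx(truth.S, rel=0.05)
        assert fit.B == pytest.approx(truth.B, rel=0.10)
        assert fit.T == pytest.approx(truth.T, rel=0.10)

    def test_noisy_recovery_median_error(self):
        truth = _params(B=2, T=6, S=100, Kp=200, Kt=300)
        rng = np.random.default_rng(77)
        errs = []
        for _ in range(100):
            prof = simulate_single_profile(truth, rng=rng)
            fit = fit_single_promoter(prof)
            errs.append(abs(fit.S - truth.S) / truth.S)
        assert np.median(errs) <= 0.15

    def test_never_below_initializer(self):
        truth = _params()
        prof = simulate_single_profile(truth, rng=5)
        m = SinglePromoterModel().fit(prof)
        from bidipol.model import _single_log_likelihood_matrix
        from scipy.special import gammaln

        counts = prof.counts.astype(float)
        idx = np.arange(counts.size)
        tss = prof.tss_bins[0]
        x0 = SinglePromoterModel._moment_init(counts, tss, idx < tss)
        ll0 = _single_log_likelihood_matrix(
            x0[None, :], counts, np.abs(idx - tss) * 20.0, idx < tss,
            gammaln(counts + 1))[0]
        assert m.log_likelihood_ >= ll0 - 1e-9

    def test_all_zero_profile_is_an_error(self):
        from bidipol import single_gene_geometry

        with pytest.raises(ValueError, match="no signal"):
            SinglePromoterModel().fit(single_gene_geometry())

    def test_tss_spike_pins_decay_scales_at_boundary(self):
        from bidipol import single_gene_geometry

        geom = single_gene_geometry(flank=400)
        counts = np.ones(geom.n_bins, dtype=int)
        counts[geom.tss_bins[0]] = 200
        m = SinglePromoterModel().fit(geom.with_counts(counts))
        assert m.boundary_flags_["Kp"] and m.boundary_flags_["Kt"]


class TestGammaHyperprior:
    def test_method_of_moments_identities(self):
        vals = np.array([2.0, 4.0, 6.0, 8.0])
        fits = [_params(B=v, T=v, S=10 * v, Kp=100 * v, Kt=100 * v)
                for v in vals] * 10
        theta = fit_hyperparams(fits)
        m, v = vals.repeat(10).mean(), np.var(vals.repeat(10), ddof=1)
        assert theta.B.alpha == pytest.approx(m * m / v)
        assert theta.B.beta == pytest.approx(v / m)

    def test_gamma_sampling_consistency(self, rng):
        draws = rng.gamma(4.0, 2.0, size=5000)
        fits = [_params(B=d, T=d, S=10 * d, Kp=100 * d, Kt=100 * d)
                for d in draws]
        theta = fit_hyperparams(fits)
        assert theta.B.alpha == pytest.approx(4.0, rel=0.10)

    def test_purity(self):
        fits = [_params(B=b, T=b, S=50 + b, Kp=100 + b, Kt=200 + b)
                for b in np.linspace(1, 5, 40)]
        t1 = GammaHyperprior().fit(fits).theta_
        t2 = GammaHyperprior().fit(fits).theta_
        assert t1 == t2

    def test_too_few_fits_rejected(self):
        with pytest.raises(ValueError, match=">= 30"):
            fit_hyperparams([_params()] * 10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_hyperparams([_params()] * 40)


class TestPairMapFit:
    def test_same_seed_same_result(self, theta, small_cohort):
        prof = small_cohort.pairs[0].profile
        Y1, lp1 = fit_pair_map(prof, theta, seed=9)
        Y2, lp2 = fit_pair_map(prof, theta, seed=9)
        assert lp1 == lp2
        np.testing.assert_array_equal(Y1.as_array(), Y2.as_array())

    def test_never_below_moment_initializer(self, theta, small_cohort):
        prof = small_cohort.pairs[1].profile
        init = PairPromoterModel._moment_init(prof)
        Y0 = PairParams.from_array(init)
        base = log_likelihood(prof, Y0) + log_prior(Y0, theta)
        _, lp = fit_pair_map(prof, theta, seed=4)
        assert lp >= base - 1e-9

    def test_gene_swap_equivariance(self, theta):
        """Mirroring the window and swapping genes preserves the optimum."""
        from bidipol import PairParams, simulate_pair_from_params

        Y = _pair(_params(S=90, Kp=120, Kt=250), _params(S=45, Kp=300, Kt=500))
        prof = simulate_pair_from_params(Y, 600, rng=3)
        mirrored = prof.with_counts(prof.counts[::-1].copy())
        _, lp_fwd = fit_pair_map(prof, theta, seed=21)
        _, lp_rev = fit_pair_map(mirrored, theta, seed=21)
        assert lp_rev == pytest.approx(lp_fwd, abs=2.0)  # optimizer tolerance

    def test_missing_theta_or_seed(self, small_cohort):
        prof = small_cohort.pairs[0].profile
        with pytest.raises(ValueError, match="theta"):
            PairPromoterModel().fit(prof)


class TestRegulatoryRegion:
    def test_closed_form_boundary(self):
        p = _params(Kp=100)
        r = extract_regulatory_region(p, tss=10_000, decay_fraction=0.9)
        # D* = 100 ln 10 = 230.26 bp, snapped outward to 240
        assert 10_000 - r.start == 240
        assert r.end - 10_000 == 20 + 20 * math.ceil(300 * math.log(10) / 20)

    def test_zero_decay_fraction_is_tss_bin(self):
        r = extract_regulatory_region(_params(), tss=10_000, decay_fraction=0.0)
        assert (r.start, r.end) == (10_000, 10_020)

    def test_extent_linear_in_Kp(self):
        r1 = extract_regulatory_region(_params(Kp=100), tss=0, decay_fraction=0.9,
                                       bin_size=1)
        r2 = extract_regulatory_region(_params(Kp=200), tss=0, decay_fraction=0.9,
                                       bin_size=1)
        assert -r2.start == pytest.approx(-2 * r1.start, abs=2)

    def test_minus_strand_mirrors_sides(self):
        p = _params(Kp=100, Kt=300)
        plus = extract_regulatory_region(p, tss=10_000, strand="+")
        minus = extract_regulatory_region(p, tss=10_000, strand="-")
        assert 10_000 - minus.start == plus.end - 10_020
        assert minus.end - 10_020 == 10_000 - plus.start

    def test_no_promoter_excess_flagged(self):
        p = SinglePromoterParams(B=5, T=2, S=5, Kp=100, Kt=100)
        with pytest.warns(UserWarning, match="S <= B"):
            r = extract_regulatory_region(p, tss=10_000)
        assert r.start == 10_000  # zero promoter-side extent


class TestClassifyPromoters:
    def _region(self, start, end, owner="gene1"):
        return RegulatoryRegion("chr1", start, end, owner)

    def test_double_with_overlap(self):
        cat, ov = classify_promoters(1100, 1500, "bipeak",
                                     [self._region(1000, 1400, "gene2"),
                                      self._region(1300, 1700, "gene1")])
        assert (cat, ov) == ("double", 100)

    def test_double_disjoint(self):
        cat, ov = classify_promoters(1100, 1600, "bipeak",
                                     [self._region(1000, 1200, "gene2"),
                                      self._region(1400, 1700, "gene1")])
        assert (cat, ov) == ("double", 0)

    @pytest.mark.parametrize(
        "span,expected",
        [((1000, 1200), "left"), ((1400, 1700), "right"), ((1000, 1700), "centre")],
    )
    def test_single_categories_by_tss_coverage(self, span, expected):
        cat, _ = classify_promoters(1100, 1600, "single",
                                    [self._region(*span, owner="shared")])
        assert cat == expected

    def test_region_covering_neither_tss_is_an_error(self):
        with pytest.raises(ValueError, match="neither"):
            classify_promoters(1100, 1600, "single",
                               [self._region(1200, 1300, "shared")])
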