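"""Empirical-Bayes normal-gamma machinery against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from sklearn.base import clone

from athleref.model import (
    DEFAULT_PERCENTILES,
    FitError,
    GroupSummary,
    Hyperparams,
    NormalGammaReferenceModel,
    ResolutionError,
    SharingRuleError,
    build_reference_table,
    fit_hyperparams,
    hpd_region,
    locate_in_reference,
    log_marginal,
    point_percentiles,
    posterior_update,
    simultaneous_cis,
    summarize_group,
)
from athleref.simulate import simulate_groups

H = Hyperparams(mu0=0.0, kappa0=1.0, alpha0=3.0, beta0=2.0)


# ---------------------------------------------------------------------------
# independent oracles


def quadrature_log_marginal(h: Hyperparams, groups: list[np.ndarray]) -> float:
    """2-D Gauss-Legendre integration of prior x likelihood over
    (mu, log tau), per group; independent of the closed form."""
    total = 0.0
    for x in groups:
        x = np.asarray(x, float)
        n = x.size
        if n == 0:
            continue
        # integration box centred on the conjugate posterior, generously wide
        kn = h.kappa0 + n
        mun = (h.kappa0 * h.mu0 + x.sum()) / kn
        an = h.alpha0 + n / 2
        bn = h.beta0 + 0.5 * np.sum((x - x.mean()) ** 2) + h.kappa0 * n * (x.mean() - h.mu0) ** 2 / (2 * kn)
        mu_scale = math.sqrt(bn / (an * kn))
        nodes, weights = np.polynomial.legendre.leggauss(400)
        mu_lo, mu_hi = mun - 45 * mu_scale, mun + 45 * mu_scale
        lt_c = math.log(an / bn)
        lt_lo, lt_hi = lt_c - 25, lt_c + 12
        mu = 0.5 * (mu_hi - mu_lo) * nodes + 0.5 * (mu_hi + mu_lo)
        lt = 0.5 * (lt_hi - lt_lo) * nodes + 0.5 * (lt_hi + lt_lo)
        wmu = 0.5 * (mu_hi - mu_lo) * weights
        wlt = 0.5 * (lt_hi - lt_lo) * weights
        MU, LT = np.meshgrid(mu, lt, indexing="ij")
        TAU = np.exp(LT)
        log_prior = (
            0.5 * (np.log(h.kappa0) + LT - math.log(2 * math.pi))
            - h.kappa0 * TAU * (MU - h.mu0) ** 2 / 2
            + h.alpha0 * math.log(h.beta0)
            - math.lgamma(h.alpha0)
            + (h.alpha0 - 1) * LT
            - h.beta0 * TAU
            + LT  # Jacobian d tau = tau d(log tau)
        )
        log_lik = (
            n / 2 * (LT - math.log(2 * math.pi))
            - TAU / 2 * ((x[:, None, None] - MU[None]) ** 2).sum(axis=0)
        )
        integrand = np.exp(log_prior + log_lik)
        total += math.log(float(wmu @ integrand @ wlt))
    return total


def sequential_posterior(h: Hyperparams, x: np.ndarray) -> tuple[float, float, float, float]:
    """One-observation-at-a-time conjugate updating (no ss term), the
    brute-force counterpart of the batch update."""
    mu, k, a, b = h.mu0, h.kappa0, h.alpha0, h.beta0
    for xi in np.asarray(x, float):
        b = b + k * (xi - mu) ** 2 / (2 * (k + 1))
        mu = (k * mu + xi) / (k + 1)
        k += 1.0
        a += 0.5
    return mu, k, a, b


# ---------------------------------------------------------------------------
# sufficient statistics


class TestSummarize:
    def test_empty_collection(self):
        s = summarize_group([])
        assert s.n == 0 and math.isnan(s.mean) and s.ss == 0.0

    def test_hand_arithmetic(self):
        s = summarize_group([5, 7])
        assert (s.n, s.mean, s.ss) == (2, 6.0, 2.0)

    def test_ss_matches_brute_force(self, rng):
        x = rng.normal(100, 5, size=57)
        s = summarize_group(x)
        brute = sum((xi - x.mean()) ** 2 for xi in x)
        assert s.ss == pytest.approx(brute, rel=1e-12)

    def test_single_value_has_zero_ss(self):
        s = summarize_group([3.3])
        assert s.n == 1 and s.ss == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([1.0, float("inf")])


# ---------------------------------------------------------------------------
# marginal likelihood


class TestLogMarginal:
    def test_empty_summaries_give_zero(self):
        assert log_marginal(H, []) == 0.0

    def test_n1_group_equals_student_t_density(self):
        # with one observation the marginal is Student-t with 2*alpha0 df,
        # location mu0, scale^2 = beta0*(kappa0+1)/(alpha0*kappa0)
        x = 1.37
        s = summarize_group([x])
        scale = math.sqrt(H.beta0 * (H.kappa0 + 1) / (H.alpha0 * H.kappa0))
        expected = stats.t.logpdf(x, df=2 * H.alpha0, loc=H.mu0, scale=scale)
        assert log_marginal(H, [s]) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("sizes", [(1,), (2,), (4,), (1, 3), (2, 2, 4)])
    def test_closed_form_matches_quadrature(self, sizes, rng):
        groups = [rng.normal(0.4, 1.2, size=n) for n in sizes]
        summaries = [summarize_group(g) for g in groups]
        closed = log_marginal(H, summaries)
        quad = quadrature_log_marginal(H, groups)
        assert closed == pytest.approx(quad, abs=1e-6)

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            Hyperparams(0.0, -1.0, 3.0, 2.0)


# ---------------------------------------------------------------------------
# empirical-Bayes fit


class TestFitHyperparams:
    def test_recovers_known_truth_within_15_percent(self, rng):
        summaries, _ = simulate_groups(H, [20] * 200, np.random.default_rng(42))
        est = fit_hyperparams(summaries)
        assert abs(est.kappa0 - H.kappa0) / H.kappa0 < 0.15
        assert abs(est.alpha0 - H.alpha0) / H.alpha0 < 0.15
        assert abs(est.beta0 - H.beta0) / H.beta0 < 0.15
        assert abs(est.mu0 - H.mu0) < 0.15 * math.sqrt(H.beta0 / ((H.alpha0 - 1) * H.kappa0))

    def test_location_equivariance_is_exact(self, rng):
        summaries, _ = simulate_groups(H, [5, 9, 14, 30], np.random.default_rng(7))
        shift = 173.2
        shifted = [
            GroupSummary(group=s.group, n=s.n, mean=s.mean + shift, ss=s.ss) for s in summaries
        ]
        a = fit_hyperparams(summaries)
        b = fit_hyperparams(shifted)
        assert b.mu0 - a.mu0 == pytest.approx(shift, abs=1e-6)
        assert b.kappa0 == pytest.approx(a.kappa0, rel=1e-6)
        assert b.alpha0 == pytest.approx(a.alpha0, rel=1e-6)

    def test_fit_is_a_local_maximum(self, rng):
        summaries, _ = simulate_groups(H, [10] * 30, np.random.default_rng(3))
        est = fit_hyperparams(summaries)
        best = log_marginal(est, summaries)
        theta = np.array([est.mu0, math.log(est.kappa0), math.log(est.alpha0), math.log(est.beta0)])
        for _ in range(100):
            pert = theta + rng.normal(0, 0.05, size=4)
            h = Hyperparams(pert[0], math.exp(pert[1]), math.exp(pert[2]), math.exp(pert[3]))
            assert log_marginal(h, summaries) <= best + 1e-7

    def test_too_few_groups_rejected(self):
        with pytest.raises(SharingRuleError):
            fit_hyperparams([summarize_group([1.0, 2.0])])

    def test_degenerate_data_rejected(self):
        summaries = [summarize_group([5.0, 5.0], group=g) for g in "ab"]
        with pytest.raises(FitError, match="identical"):
            fit_hyperparams(summaries)


# ---------------------------------------------------------------------------
# conjugate posterior


class TestPosteriorUpdate:
    def test_mean_at_prior_location_does_not_move(self):
        s = summarize_group([H.mu0 - 1.0, H.mu0 + 1.0])
        post = posterior_update(H, s)
        assert post.mu_n == pytest.approx(H.mu0)
        assert post.beta_n == pytest.approx(H.beta0 + s.ss / 2)
        assert post.kappa_n == H.kappa0 + 2 and post.alpha_n == H.alpha0 + 1

    def test_batch_equals_sequential_updating(self, rng):
        x = rng.normal(2.0, 1.5, size=9)
        post = posterior_update(H, summarize_group(x))
        mu, k, a, b = sequential_posterior(H, x)
        assert post.mu_n == pytest.approx(mu, rel=1e-12)
        assert post.kappa_n == pytest.approx(k)
        assert post.alpha_n == pytest.approx(a)
        assert post.beta_n == pytest.approx(b, rel=1e-12)

    def test_large_n_pulls_mean_to_sample_mean(self, rng):
        x = rng.normal(10.0, 1.0, size=5000)
        post = posterior_update(H, summarize_group(x))
        assert post.mu_n == pytest.approx(x.mean(), abs=1e-2)

    def test_sharing_rule_rejects_singletons(self):
        with pytest.raises(SharingRuleError):
            posterior_update(H, summarize_group([1.0]))

    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=2, max_size=12))
    def test_shrinkage_never_overshoots_prior(self, values):
        s = summarize_group(values)
        post = posterior_update(H, s)
        assert abs(post.mu_n - H.mu0) <= abs(s.mean - H.mu0) + 1e-12


# ---------------------------------------------------------------------------
# percentile points


class TestPointPercentiles:
    POST = posterior_update(H, summarize_group([9.0, 10.0, 11.0]))

    def test_median_is_posterior_mean(self):
        (p, point), = point_percentiles(self.POST, [50.0])
        assert point == pytest.approx(self.POST.mu_n)

    def test_normal_quantile_oracle(self):
        from athleref.model import Posterior

        post = Posterior(group="g", n=4, mu_n=10.0, kappa_n=5.0, alpha_n=3.0, beta_n=8.0)
        pts = dict(point_percentiles(post, [95.0]))
        assert pts[95.0] == pytest.approx(10.0 + 2.0 * stats.norm.ppf(0.95))

    def test_points_strictly_increase_with_rank(self):
        pts = [v for _, v in point_percentiles(self.POST, DEFAULT_PERCENTILES)]
        assert all(a < b for a, b in zip(pts, pts[1:]))

    def test_alpha_at_most_one_rejected(self):
        from athleref.model import Posterior

        post = Posterior(group="g", n=2, mu_n=0.0, kappa_n=3.0, alpha_n=0.9, beta_n=1.0)
        with pytest.raises(ValueError, match="larger group or a stronger prior"):
            point_percentiles(post, [50.0])

    def test_alternative_variance_estimator(self):
        pts_pm = dict(point_percentiles(self.POST, [95.0], "posterior_mean"))
        pts_ip = dict(point_percentiles(self.POST, [95.0], "inverse_mean_precision"))
        # beta/alpha < beta/(alpha-1): the alternative is tighter
        assert pts_ip[95.0] < pts_pm[95.0]


# ---------------------------------------------------------------------------
# HPD region and simultaneous CIs


@pytest.fixture(scope="module")
def posterior():
    return posterior_update(H, summarize_group([0.3, -0.8, 1.4, 0.9, -0.1, 0.6, 2.0, 1.1]))


@pytest.fixture(scope="module")
def region(posterior):
    return hpd_region(posterior, level=0.95, grid=(120, 120))


class TestHpdRegion:
    def test_contained_mass_matches_monte_carlo(self, posterior, region):
        # independent route: sample (mu, tau) from the posterior and count
        # the fraction whose density reaches the region threshold
        rng = np.random.default_rng(99)
        tau = rng.gamma(posterior.alpha_n, 1.0 / posterior.beta_n, size=200_000)
        mu = rng.normal(posterior.mu_n, 1.0 / np.sqrt(posterior.kappa_n * tau))
        frac = np.mean(region.log_density_at(mu, tau) >= region.log_threshold)
        assert frac == pytest.approx(0.95, abs=0.005)
        assert region.contained_mass == pytest.approx(0.95, abs=0.005)

    def test_posterior_mode_inside_region_at_any_level(self, posterior):
        # mode of (mu, log tau) density: mu = mu_n, tau = (alpha_n + 1/2)/(beta_n)
        for level in (0.2, 0.5, 0.95):
            reg = hpd_region(posterior, level=level, grid=(80, 80))
            mode_tau = (posterior.alpha_n + 0.5) / posterior.beta_n
            assert reg.contains(posterior.mu_n, mode_tau)

    def test_regions_nest_with_level(self, posterior):
        lo = hpd_region(posterior, level=0.5, grid=(100, 100))
        hi = hpd_region(posterior, level=0.95, grid=(100, 100))
        assert lo.log_threshold > hi.log_threshold
        assert np.all(hi.mask[lo.mask])

    def test_too_coarse_grid_rejected(self, posterior):
        with pytest.raises(ValueError, match="at least 50x50"):
            hpd_region(posterior, grid=(20, 20))

    def test_too_narrow_span_raises_resolution_error(self, posterior):
        with pytest.raises(ResolutionError):
            hpd_region(posterior, level=0.999, span_sds=1.0, grid=(60, 60))


class TestSimultaneousCis:
    def test_extremes_match_exhaustive_grid_scan(self, region):
        cis = simultaneous_cis(region, DEFAULT_PERCENTILES)
        cells = np.argwhere(region.mask)
        for p, lo, hi in cis:
            z = stats.norm.ppf(p / 100)
            vals = [
                region.mu[i] + z / math.sqrt(math.exp(region.log_tau[j])) for i, j in cells
            ]
            assert lo == pytest.approx(min(vals), rel=1e-12)
            assert hi == pytest.approx(max(vals), rel=1e-12)

    def test_median_interval_contains_posterior_mean(self, posterior, region):
        (p, lo, hi), = simultaneous_cis(region, [50.0])
        assert lo <= posterior.mu_n <= hi

    def test_interval_widens_with_extremity(self, region):
        cis = {p: hi - lo for p, lo, hi in simultaneous_cis(region, DEFAULT_PERCENTILES)}
        assert cis[5.0] > cis[50.0] and cis[95.0] > cis[50.0]


# ---------------------------------------------------------------------------
# reference tables and the estimator


def _toy_frame(rng, n_sports=6, n=25, loc=50.0, scale=5.0):
    rows = []
    for s in range(n_sports):
        mu = loc + rng.normal(0, 3)
        for v in rng.normal(mu, scale, size=n):
            rows.append({"sport": f"s{s}", "sex": "male", "y": v})
    return pd.DataFrame(rows)


class TestBuildReferenceTable:
    def test_log_scale_median_equals_exponentiated_log_median(self, rng):
        frame = _toy_frame(rng)
        frame["y"] = np.exp(frame["y"] / 25.0)
        direct = build_reference_table(frame, "y", log_scale=True, grid=(60, 60))
        logged = frame.assign(y=np.log(frame["y"]))
        on_log = build_reference_table(logged, "y", log_scale=False, grid=(60, 60))
        for sport in direct.estimates["sport"].unique():
            med_direct = direct.row(sport)[50.0]
            med_log = on_log.row(sport)[50.0]
            assert med_direct == pytest.approx(math.exp(med_log), rel=1e-9)

    def test_log_scale_rejects_nonpositive_values(self, rng):
        frame = _toy_frame(rng)
        frame.loc[0, "y"] = -1.0
        with pytest.raises(ValueError, match="log scale"):
            build_reference_table(frame, "y", log_scale=True)

    def test_small_group_is_shrunk_toward_pool(self, rng):
        frame = _toy_frame(rng, n_sports=4, n=80, loc=50.0)
        tiny = pd.DataFrame(
            {"sport": "tiny", "sex": "male", "y": [70.0, 71.0]}
        )  # far from the pool
        table = build_reference_table(pd.concat([frame, tiny]), "y", grid=(60, 60))
        med = table.row("tiny")[50.0]
        pool = frame["y"].mean()
        assert pool < med < 70.5  # pulled below its own mean, above the pool

    def test_reporting_and_sharing_gates(self, rng):
        frame = _toy_frame(rng, n_sports=3, n=20)
        frame = pd.concat(
            [
                frame,
                pd.DataFrame({"sport": "five", "sex": "male", "y": rng.normal(50, 5, 5)}),
                pd.DataFrame({"sport": "one", "sex": "male", "y": [50.0]}),
            ]
        )
        table = build_reference_table(frame, "y", grid=(60, 60))
        est = table.estimates
        assert "one" not in set(est["sport"])  # below the sharing gate
        assert not est.loc[est["sport"] == "five", "reported"].any()  # below reporting gate
        assert est.loc[est["sport"] == "s0", "reported"].all()

    def test_points_monotone_and_bracketed_by_cis(self, rng):
        table = build_reference_table(_toy_frame(rng), "y", grid=(60, 60))
        for _, g in table.estimates.groupby("sport"):
            g = g.sort_values("p")
            assert g["point"].is_monotonic_increasing
            assert (g["lo"] <= g["point"] + 1e-12).all()
            assert (g["point"] <= g["hi"] + 1e-12).all()

    def test_prior_weight_is_kappa0_in_persons(self, rng):
        table = build_reference_table(_toy_frame(rng), "y", grid=(60, 60))
        assert table.prior_weight == table.hyperparams.kappa0 > 0


class TestLocate:
    ROW = {5.0: 8.0, 25.0: 12.9, 50.0: 16.3}

    def test_discussion_style_example_brackets_and_nearest(self):
        res = locate_in_reference(13.0, self.ROW)
        assert res.bracket == (25.0, 50.0)
        assert res.nearest == 25.0

    def test_below_and_above_range(self):
        assert locate_in_reference(7.0, self.ROW).band == "<5"
        assert locate_in_reference(20.0, self.ROW).band == ">50"

    def test_exact_point_maps_to_its_rank(self):
        assert locate_in_reference(16.3, self.ROW).nearest == 50.0

    def test_non_monotone_row_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            locate_in_reference(10.0, {5.0: 8.0, 25.0: 7.0, 50.0: 16.0})


class TestEstimator:
    def test_fit_predict_and_sklearn_protocol(self, rng):
        frame = _toy_frame(rng)
        est = NormalGammaReferenceModel(grid=(60, 60))
        cloned = clone(est)  # param round-trip via get_params/set_params
        assert cloned.get_params()["grid"] == (60, 60)
        est.fit(frame["y"].to_numpy(), frame["sport"].to_numpy())
        assert hasattr(est, "hyperparams_") and est.prior_weight_ > 0
        ranks = est.predict([est.posteriors_["s0"].mu_n], ["s0"])
        assert ranks[0] == 50.0
        res = est.locate(est.posteriors_["s0"].mu_n, "s0")
        assert res.bracket is not None

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            NormalGammaReferenceModel().predict([1.0], ["a"])
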