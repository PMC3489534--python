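"""Censored/MCAR likelihood, information filtering, imputation, p-adjustment."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lcmsprep.core import ProteinMap, StudyDesign
from lcmsprep.missing import (MissingnessParams, NonIdentifiableError,
                              ProteinModelFit, adjust_pvalues, cell_loglik,
                              classify_missing, estimate_missingness_params,
                              fit_protein_ml, fit_protein_quick,
                              greedy_select_peptides, impute_model_based,
                              impute_naive, information_content,
                              observed_information)

from .conftest import balanced_design, make_matrix

NO_MISS = MissingnessParams(0.0, -math.inf)


class TestCellLoglik:
    def test_missing_with_disabled_cutoff_is_log_pi(self):
        params = MissingnessParams(0.3, -math.inf)
        assert cell_loglik(None, 0.0, 1.0, params) == pytest.approx(math.log(0.3))

    def test_missing_at_cutoff_mean_is_log_half(self):
        params = MissingnessParams(0.0, 0.0)
        assert cell_loglik(None, 0.0, 1.0, params) == pytest.approx(
            math.log(0.5), abs=1e-12)

    def test_missing_mixture_value(self):
        # log(0.1 + 0.9 * Phi(-1)) evaluated with the exact normal CDF
        params = MissingnessParams(0.1, -1.0)
        expected = math.log(0.1 + 0.9 * stats.norm.cdf(-1.0))
        got = cell_loglik(None, 0.0, 1.0, params)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(-1.41555, abs=1e-4)

    def test_observed_value_density(self):
        params = MissingnessParams(0.2, -1.0)
        got = cell_loglik(1.3, 0.5, 2.0, params)
        expected = math.log(0.8) + stats.norm.logpdf(1.3, 0.5, 2.0)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_observed_with_pi_one_warns_impossible(self):
        params = MissingnessParams(1.0, -math.inf)
        with pytest.warns(UserWarning, match="impossible"):
            assert cell_loglik(0.0, 0.0, 1.0, params) == -math.inf

    def test_probability_conservation_without_mcar(self):
        # P(observed & y in (c, inf)) + P(missing) = 1 when pi = 0
        params = MissingnessParams(0.0, -0.7)
        mu, sigma = 0.3, 1.4
        from scipy.integrate import quad
        dens = lambda y: math.exp(cell_loglik(y, mu, sigma, params))
        obs_mass, _ = quad(dens, params.cutoff, 40.0)
        miss_mass = math.exp(cell_loglik(None, mu, sigma, params))
        assert obs_mass + miss_mass == pytest.approx(1.0, abs=1e-8)


def _protein_matrix(values, prefix="PEP"):
    return make_matrix(values, prefix=prefix)


class TestFitProteinML:
    def test_complete_data_single_peptide_matches_least_squares(self):
        # with one peptide the heteroscedastic ML reduces exactly to OLS
        rng = np.random.default_rng(1)
        design = balanced_design(6)
        y = rng.normal(0, 1, size=(1, 12))
        fit = fit_protein_ml(_protein_matrix(y), design, NO_MISS)
        g1, g2 = y[0, :6].mean(), y[0, 6:].mean()
        assert fit.treat_difference() == pytest.approx(g1 - g2, abs=1e-6)
        assert fit.protein_mean == pytest.approx(y.mean(), abs=1e-6)
        assert fit.resid_sd[0] ** 2 == pytest.approx(
            np.mean((y[0] - np.where(np.arange(12) < 6, g1, g2)) ** 2),
            abs=1e-6)

    def test_complete_data_multi_peptide_matches_irls_oracle(self):
        # independent IRLS oracle for the heteroscedastic ML fixed point
        rng = np.random.default_rng(2)
        design = balanced_design(8)
        J, n = 3, 16
        y = (np.array([[1.0], [0.0], [-1.0]])
             + np.array([0.4] * 8 + [-0.4] * 8)[None, :]
             + rng.normal(0, [[0.3], [0.8], [1.5]], size=(J, n)))
        fit = fit_protein_ml(_protein_matrix(y), design, NO_MISS)
        # oracle: alternate per-peptide group contrasts and variance weights
        d_j = y[:, :8].mean(1) - y[:, 8:].mean(1)
        a_j = (y[:, :8].mean(1) + y[:, 8:].mean(1)) / 2
        d = d_j.mean()
        for _ in range(200):
            resid = y - a_j[:, None] - np.array([d / 2] * 8 + [-d / 2] * 8)
            s2 = np.mean(resid**2, axis=1)
            w = n / s2
            d = float(np.sum(w * d_j) / np.sum(w))
        assert fit.treat_difference() == pytest.approx(d, abs=1e-6)

    def test_all_missing_is_non_identifiable(self, two_group_design):
        m = _protein_matrix(np.full((2, 6), math.nan))
        with pytest.raises(NonIdentifiableError):
            fit_protein_ml(m, two_group_design, MissingnessParams(0.1, 0.0))

    def test_group_without_observations_is_non_identifiable(self):
        design = balanced_design(3)
        vals = np.array([[1.0, 2.0, 1.5, math.nan, math.nan, math.nan]])
        with pytest.raises(NonIdentifiableError, match="group"):
            fit_protein_ml(_protein_matrix(vals), design,
                           MissingnessParams(0.1, 0.0))

    def test_censored_fit_beats_ignoring_censoring(self):
        # treating censored cells as absent biases the mean upward; the
        # censored likelihood corrects most of that bias
        rng = np.random.default_rng(3)
        design = balanced_design(25)
        errs_ml, errs_ls = [], []
        for rep in range(30):
            y = 0.0 + rng.normal(0, 0.6, size=(1, 50))
            c = np.quantile(y, 0.35)
            obs = np.where(y < c, math.nan, y)
            m = _protein_matrix(obs)
            fit = fit_protein_ml(m, design, MissingnessParams(0.0, c))
            errs_ml.append(fit.protein_mean - 0.0)
            errs_ls.append(np.nanmean(obs) - 0.0)
        assert abs(np.mean(errs_ml)) < 0.35 * abs(np.mean(errs_ls))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        design = balanced_design(5)
        y = rng.normal(0, 1, size=(2, 10))
        y[0, 3] = y[1, 7] = math.nan
        params = MissingnessParams(0.1, -0.5)
        f1 = fit_protein_ml(_protein_matrix(y), design, params, seed=9)
        f2 = fit_protein_ml(_protein_matrix(y), design, params, seed=9)
        assert f1.loglik == f2.loglik
        np.testing.assert_array_equal(f1.resid_sd, f2.resid_sd)


class TestInformationContent:
    def _single_peptide_fit(self, n, sigma, rng):
        design = balanced_design(n)
        y = rng.normal(0, sigma, size=(1, 2 * n))
        m = _protein_matrix(y)
        fit = fit_protein_ml(m, design, NO_MISS)
        # evaluate the information at the fitted means but the *known* sigma
        fit_known = ProteinModelFit(
            "p", fit.peptide_ids, fit.groups, fit.protein_mean,
            fit.peptide_offset, fit.treat_effect, np.array([sigma]),
            0.0, np.zeros(1), True, 2 * n, group_index=fit.group_index)
        fit_known.info_matrix = observed_information(m, design, NO_MISS,
                                                     fit_known)
        return fit_known

    def test_two_group_closed_form(self):
        rng = np.random.default_rng(5)
        n, sigma = 7, 0.8
        fit = self._single_peptide_fit(n, sigma, rng)
        assert information_content(fit) == pytest.approx(
            n / (2 * sigma**2), abs=1e-8)

    def test_information_linear_in_sample_size(self):
        rng = np.random.default_rng(6)
        i1 = information_content(self._single_peptide_fit(5, 1.0, rng))
        i2 = information_content(self._single_peptide_fit(10, 1.0, rng))
        assert i2 == pytest.approx(2.0 * i1, abs=1e-8)

    def test_zero_for_unobserved_group(self):
        design = balanced_design(3)
        vals = np.array([[0.1, -0.2, 0.05, math.nan, math.nan, math.nan],
                         [0.2, 0.1, -0.1, math.nan, math.nan, math.nan]])
        m = _protein_matrix(vals)
        params = MissingnessParams(0.5, -math.inf)  # pure MCAR: no info in missing
        fit = fit_protein_quick(m, design, params) if False else None
        sel, info, filtered = greedy_select_peptides(m, design, params)
        assert filtered and info == 0.0 and sel == []

    def test_nonincreasing_under_observation_deletion(self):
        rng = np.random.default_rng(7)
        design = balanced_design(4)
        y = rng.normal(0, 1, size=(1, 8))
        m_full = _protein_matrix(y)
        fit_full = fit_protein_ml(m_full, design, NO_MISS)
        info_full = information_content(fit_full)
        y2 = y.copy()
        y2[0, 0] = math.nan
        fit_less = fit_protein_ml(
            _protein_matrix(y2), design,
            MissingnessParams(0.5, -math.inf))  # MCAR deletion
        # evaluate both at the same known sigma to isolate the data effect
        sd = fit_full.resid_sd
        for f, mm in ((fit_full, m_full), (fit_less, _protein_matrix(y2))):
            f.resid_sd = sd
            f.info_matrix = observed_information(
                mm, design, MissingnessParams(0.5, -math.inf), f)
        assert information_content(fit_less) < information_content(fit_full)


class TestGreedySelection:
    def test_matches_exhaustive_search_on_small_proteins(self):
        from lcmsprep.missing import subset_information

        rng = np.random.default_rng(8)
        design = balanced_design(4)
        params = MissingnessParams(0.1, -1.5)
        for rep in range(6):
            J = int(rng.integers(2, 6))
            y = rng.normal(0, 1, size=(J, 8))
            y[rng.random(y.shape) < 0.2] = math.nan
            if np.isnan(y).all(axis=1).all():
                continue
            m = _protein_matrix(y)
            sel, info, filtered = greedy_select_peptides(m, design, params)
            try:
                full = fit_protein_quick(m, design, params)
            except (NonIdentifiableError, np.linalg.LinAlgError):
                assert filtered
                continue
            best = max((subset_information(m, design, params, full, list(c))
                        for r in range(1, J + 1)
                        for c in itertools.combinations(m.peptide_ids, r)),
                       default=0.0)
            if filtered:
                assert best <= 1e-12
            else:
                assert info == pytest.approx(best, rel=1e-8)

    def test_fully_observed_exchangeable_peptides_all_selected(self):
        rng = np.random.default_rng(9)
        design = balanced_design(5)
        y = rng.normal(0, 1.0, size=(3, 10))
        m = _protein_matrix(y)
        sel, info, filtered = greedy_select_peptides(m, design, NO_MISS)
        assert not filtered
        assert sel == m.peptide_ids

    def test_all_missing_peptide_excluded(self):
        rng = np.random.default_rng(10)
        design = balanced_design(5)
        y = rng.normal(0, 1, size=(2, 10))
        y[1, :] = math.nan
        sel, info, filtered = greedy_select_peptides(
            _protein_matrix(y), design, MissingnessParams(0.2, -math.inf))
        assert sel == ["PEP1"] and not filtered


class TestClassification:
    def _fit_for(self, m, design, params):
        return fit_protein_quick(m, design, params)

    def test_pi_zero_labels_censored(self):
        design = balanced_design(4)
        y = np.random.default_rng(11).normal(0, 1, size=(1, 8))
        y[0, 2] = math.nan
        m = _protein_matrix(y)
        params = MissingnessParams(0.0, 0.5)
        cls = classify_missing(m, self._fit_for(m, design, params), params)
        assert np.all(cls.posterior == 1.0) and np.all(cls.censored)

    def test_disabled_cutoff_labels_mcar(self):
        design = balanced_design(4)
        y = np.random.default_rng(12).normal(0, 1, size=(1, 8))
        y[0, 5] = math.nan
        m = _protein_matrix(y)
        params = MissingnessParams(0.2, -math.inf)
        cls = classify_missing(m, self._fit_for(m, design, params), params)
        assert np.all(cls.posterior == 0.0) and not cls.censored.any()

    def test_posterior_value(self):
        # pi=0.1 and Phi((c-mu)/sigma)=Phi(-1): posterior = 0.58812...
        phi = stats.norm.cdf(-1.0)
        expected = 0.9 * phi / (0.1 + 0.9 * phi)
        design = balanced_design(4)
        y = np.zeros((1, 8))
        y[0, 0] = math.nan
        m = _protein_matrix(y)
        fit = ProteinModelFit("p", ["PEP1"], ["G1", "G2"], 0.0,
                              np.zeros(1), np.zeros(2), np.array([1.0]),
                              0.0, np.eye(3), True, 7,
                              group_index=design.group_index())
        cls = classify_missing(m, fit, MissingnessParams(0.1, -1.0))
        assert cls.posterior[0] == pytest.approx(expected, abs=1e-10)
        assert cls.posterior[0] == pytest.approx(0.58814, abs=1e-4)


class TestImputation:
    def _setup(self, seed=13, n_per_group=10, censor_q=0.25):
        rng = np.random.default_rng(seed)
        design = balanced_design(n_per_group)
        y = rng.normal(20, 1, size=(3, 2 * n_per_group))
        c = np.quantile(y, censor_q)
        obs = np.where(y < c, math.nan, y)
        m = _protein_matrix(obs)
        pmap = ProteinMap({p: "PR1" for p in m.peptide_ids})
        params = MissingnessParams(0.0, c)
        fits = {"PR1": fit_protein_quick(m, design, params)}
        return m, design, pmap, params, fits

    def test_censored_draws_bounded_by_cutoff(self):
        m, design, pmap, params, fits = self._setup()
        res = impute_model_based(m, fits, pmap, design, params, seed=1)
        assert not res.matrix.mask.any()
        imputed = res.matrix.values[m.mask]
        assert np.all(imputed <= params.cutoff)

    def test_truncated_normal_mean(self):
        # mean of N(0,1) truncated to (-inf, 0] is -sqrt(2/pi)
        rng = np.random.default_rng(14)
        draws = stats.truncnorm.rvs(-np.inf, 0.0, loc=0.0, scale=1.0,
                                    size=100_000, random_state=rng)
        assert draws.mean() == pytest.approx(-math.sqrt(2 / math.pi), abs=0.01)

    def test_identical_seed_identical_output(self):
        m, design, pmap, params, fits = self._setup()
        a = impute_model_based(m, fits, pmap, design, params, seed=5)
        b = impute_model_based(m, fits, pmap, design, params, seed=5)
        np.testing.assert_array_equal(a.matrix.values, b.matrix.values)

    def test_unfitted_protein_cells_reported_skipped(self):
        m, design, pmap, params, _ = self._setup()
        res = impute_model_based(m, {}, pmap, design, params, seed=1)
        assert len(res.skipped_cells) == int(m.mask.sum())
        assert np.array_equal(res.matrix.mask, m.mask)


class TestNaiveImputation:
    def test_row_mean(self):
        m = make_matrix([[2.0, 4.0, math.nan]])
        out = impute_naive(m, "row_mean")
        assert out.values[0, 2] == pytest.approx(3.0)

    def test_min_observed_uses_global_minimum(self):
        m = make_matrix([[5.0, math.nan], [1.5, 7.0]])
        out = impute_naive(m, "min_observed")
        assert out.values[0, 1] == 1.5

    def test_normal_draw_matches_row_moments(self):
        rng = np.random.default_rng(15)
        row = rng.normal(10, 2, size=50)
        reps = []
        for s in range(400):
            vals = np.concatenate([row, [math.nan]])[None, :]
            out = impute_naive(make_matrix(vals), "normal_draw", seed=s)
            reps.append(out.values[0, -1])
        se = row.std(ddof=1) / math.sqrt(len(reps)) * math.sqrt(len(reps))
        assert np.mean(reps) == pytest.approx(row.mean(),
                                              abs=3 * row.std(ddof=1) / 20)

    def test_group_normal_draw_uses_group_moments(self):
        design = balanced_design(25)
        row = np.concatenate([np.full(25, 0.0), np.full(25, 8.0)])
        row[0] = math.nan
        row[-1] = math.nan
        row[1:25] = np.random.default_rng(16).normal(0, 0.5, 24)
        row[25:49] = np.random.default_rng(17).normal(8, 0.5, 24)
        out = impute_naive(make_matrix(row[None, :]), "group_normal_draw",
                           seed=3, design=design)
        assert abs(out.values[0, 0] - 0.0) < 3.0
        assert abs(out.values[0, -1] - 8.0) < 3.0

    def test_errors_name_the_peptide(self):
        m = make_matrix([[math.nan, math.nan], [1.0, 2.0]])
        with pytest.raises(ValueError, match="P1"):
            impute_naive(m, "row_mean")
        m2 = make_matrix([[1.0, math.nan], [1.0, 2.0]])
        with pytest.raises(ValueError, match="P1"):
            impute_naive(m2, "normal_draw")


class TestEstimateMissingness:
    def test_complete_matrix_gives_pure_defaults(self):
        m = make_matrix(np.ones((3, 4)))
        p = estimate_missingness_params(m)
        assert p.pi_mcar == 0.0 and p.cutoff == -math.inf

    def test_recovers_mcar_rate_from_top_quartile(self):
        rng = np.random.default_rng(18)
        vals = rng.normal(20, 3, size=(2000, 10))
        mask = rng.random(vals.shape) < 0.05
        vals[mask] = math.nan
        p = estimate_missingness_params(make_matrix(vals))
        assert p.pi_mcar == pytest.approx(0.05, abs=0.02)

    def test_all_missing_sample_rejected(self):
        vals = np.array([[1.0, math.nan], [2.0, math.nan]])
        with pytest.raises(ValueError, match="S2"):
            estimate_missingness_params(make_matrix(vals))


class TestAdjustPvalues:
    def test_uniform_input_nearly_unchanged(self):
        rng = np.random.default_rng(19)
        p = rng.random(2000)
        adj, lam = adjust_pvalues(p)
        assert lam == pytest.approx(1.0, abs=0.1)
        assert np.max(np.abs(adj - p)) < 0.05

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_ranks_preserved(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(200) ** 2  # skewed toward small values
        adj, _ = adjust_pvalues(p, min_tail=10)
        assert np.array_equal(np.argsort(adj), np.argsort(p))

    def test_inflated_input_deflated(self):
        # -log p stretched by 1.5: lambda detects inflation and the monotone
        # rescale pushes every p-value back toward (never past) uniform
        rng = np.random.default_rng(20)
        p = rng.random(5000) ** 1.5
        adj, lam = adjust_pvalues(p)
        assert lam > 1.1
        assert np.all(adj >= p)
        # the adjusted null tail is close to its uniform share
        assert abs(np.mean(adj > 0.5) - 0.5) < 0.05

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            adjust_pvalues([0.2, 1.5] + [0.8] * 60)

    def test_too_few_tail_values_rejected(self):
        with pytest.raises(ValueError, match="at least 50"):
            adjust_pvalues([0.01] * 100)
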