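import math

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import gamma as gamma_dist

from copulatrial import _kernels
from copulatrial.inference import (
    MCMCConfig,
    PriorSpec,
    TrialData,
    log_likelihood,
    log_prior,
    posterior_dose_summaries,
    sample_posterior,
)
from copulatrial.model_core import (
    CopulaSpec,
    DoseGrid,
    MarginalPair,
    MarginalParams,
    braun_true_marginals,
    joint_table,
    marginal_curves,
)


def naive_loglik(params, copula, data, grid):
    """Independent oracle: per-subject loop over joint-table cells."""
    pairs = marginal_curves(params, grid)
    total = 0.0
    for z, yt, ye in zip(data.z, data.y_T, data.y_E):
        t = joint_table(pairs[list(grid.levels).index(z)], copula)
        cell = {(1, 1): t.p11, (1, 0): t.p10, (0, 1): t.p01, (0, 0): t.p00}[(yt, ye)]
        total += math.log(cell)
    return total


@pytest.fixture()
def small_data():
    rng = np.random.default_rng(7)
    n = 44
    z = rng.integers(1, 5, size=n)
    return TrialData(z, rng.integers(0, 2, size=n), rng.integers(0, 2, size=n))


class TestTrialData:
    def test_counts_match_bruteforce(self, small_data, grid):
        counts = small_data.counts(grid)
        for k, z in enumerate(grid.levels):
            for j, (yt, ye) in enumerate([(1, 1), (1, 0), (0, 1), (0, 0)]):
                expected = int(
                    np.sum((small_data.z == z) & (small_data.y_T == yt) & (small_data.y_E == ye))
                )
                assert counts[k, j] == expected
        assert counts.sum() == len(small_data)

    def test_validation(self):
        with pytest.raises(ValueError):
            TrialData([1, 2], [0, 1], [0])
        with pytest.raises(ValueError):
            TrialData([0], [0], [0])
        with pytest.raises(ValueError):
            TrialData([1], [2], [0])

    def test_extend(self):
        d = TrialData.empty().extend([1, 2], [0, 1], [1, 0])
        assert len(d) == 2
        assert list(d.z) == [1, 2]


class TestLogLikelihood:
    def test_single_record_independence(self, grid):
        params = MarginalParams(-3.0, 0.5, -1.0, 0.8)
        data = TrialData([1], [1], [1])
        got = log_likelihood(params, CopulaSpec("independence"), data, grid)
        pair = marginal_curves(params, grid)[0]
        assert got == pytest.approx(math.log(pair.pi_T) + math.log(pair.pi_E), abs=1e-12)

    def test_braun_half_equals_independence(self, small_data, grid):
        params = MarginalParams(-2.0, 0.6, -1.0, 0.4, 0.05)
        a = log_likelihood(params, CopulaSpec("braun", 0.5), small_data, grid)
        b = log_likelihood(params, CopulaSpec("independence"), small_data, grid)
        assert a == pytest.approx(b, abs=1e-10)

    @pytest.mark.parametrize(
        "copula",
        [CopulaSpec("independence"), CopulaSpec("braun", 0.8), CopulaSpec("gumbel", -0.4)],
    )
    def test_counts_evaluation_matches_naive_loop(self, copula, small_data, grid):
        params = MarginalParams(-2.5, 0.7, -1.2, 0.5, -0.05)
        assert log_likelihood(params, copula, small_data, grid) == pytest.approx(
            naive_loglik(params, copula, small_data, grid), abs=1e-9
        )

    def test_permutation_invariance(self, small_data, grid):
        params = MarginalParams(-2.0, 0.4, -1.0, 0.6)
        perm = np.random.default_rng(1).permutation(len(small_data))
        shuffled = TrialData(small_data.z[perm], small_data.y_T[perm], small_data.y_E[perm])
        c = CopulaSpec("gumbel", 0.3)
        assert log_likelihood(params, c, small_data, grid) == log_likelihood(params, c, shuffled, grid)

    def test_empty_data_rejected(self, grid):
        with pytest.raises(ValueError):
            log_likelihood(MarginalParams(-2, 0.5, -1, 0.5), CopulaSpec("independence"), TrialData.empty(), grid)


class TestLogPrior:
    def test_ps1_slope_prior_moments(self):
        # Gamma(1/4, 1/4): mean 1, sd 2
        d = gamma_dist(0.25, scale=4.0)
        assert d.mean() == pytest.approx(1.0)
        assert d.std() == pytest.approx(2.0)

    def test_ps3_slope_prior_moments(self):
        # Gamma(1/25, 1/25): mean 1, sd 5
        d = gamma_dist(0.04, scale=25.0)
        assert d.mean() == pytest.approx(1.0)
        assert d.std() == pytest.approx(5.0)

    def test_psi_outside_support(self, ps1):
        params = MarginalParams(-3.0, 1.0, -1.0, 1.0)
        # construct an out-of-support spec bypassing CopulaSpec validation
        spec = CopulaSpec.__new__(CopulaSpec)
        object.__setattr__(spec, "family", "braun")
        object.__setattr__(spec, "psi", 1.5)
        assert log_prior(params, spec, ps1) == -np.inf

    def test_presets(self):
        ps2 = PriorSpec.preset("PS2")
        assert ps2.b0T_sd == 5.0 and ps2.slope_shape_T == 0.25
        ps4 = PriorSpec.preset("ps4")
        assert ps4.b0E_sd == 5.0 and ps4.slope_rate_E == 0.04
        with pytest.raises(ValueError):
            PriorSpec.preset("PS9")


class TestKernelConsistency:
    """The compiled density must agree with the reference python route."""

    @pytest.mark.parametrize(
        "family,code,psi_nat",
        [("braun", _kernels.BRAUN, 0.7), ("gumbel", _kernels.GUMBEL, -0.3), ("independence", _kernels.INDEPENDENCE, None)],
    )
    def test_loglik_agreement(self, family, code, psi_nat, small_data, grid, ps1):
        params = MarginalParams(-2.2, 0.55, -0.9, 0.35, 0.08)
        spec = CopulaSpec(family, psi_nat)
        x = np.array(
            [
                params.beta0_T,
                math.log(params.beta1_T),
                params.beta0_E,
                math.log(params.beta1_E),
                params.beta2_E,
                0.0 if psi_nat is None else (logit(psi_nat) if family == "braun" else logit((psi_nat + 1) / 2)),
            ]
        )
        got = _kernels.log_likelihood_counts(x, small_data.counts(grid).astype(float), code)
        want = log_likelihood(params, spec, small_data, grid)
        assert got == pytest.approx(want, abs=1e-9)

    def test_prior_plus_jacobian_agreement(self, ps1):
        params = MarginalParams(-2.2, 0.55, -0.9, 0.35, 0.08)
        psi = 0.7
        x = np.array([-2.2, math.log(0.55), -0.9, math.log(0.35), 0.08, logit(psi)])
        got = _kernels.log_prior_jacobian(x, ps1.as_vector(), _kernels.BRAUN)
        want = log_prior(params, CopulaSpec("braun", psi), ps1)
        # jacobians: du = ds/s for both slopes, dpsi = e(1-e) dv for the logit map
        want += math.log(0.55) + math.log(0.35) + math.log(psi * (1 - psi))
        assert got == pytest.approx(want, abs=1e-9)


class TestSamplePosterior:
    def test_determinism(self, fixed_design_data, ps1, fast_mcmc):
        a = sample_posterior(fixed_design_data, "braun", ps1, fast_mcmc, seed=42)
        b = sample_posterior(fixed_design_data, "braun", ps1, fast_mcmc, seed=42)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.acceptance_rates == b.acceptance_rates

    def test_seed_changes_draws(self, fixed_design_data, ps1, fast_mcmc):
        a = sample_posterior(fixed_design_data, "braun", ps1, fast_mcmc, seed=1)
        b = sample_posterior(fixed_design_data, "braun", ps1, fast_mcmc, seed=2)
        assert not np.array_equal(a.draws, b.draws)

    @pytest.mark.parametrize("family", ["braun", "gumbel", "independence"])
    def test_draw_support_and_acceptance(self, family, fixed_design_data, ps1, family_draws=None):
        d = sample_posterior(fixed_design_data, family, ps1, MCMCConfig(burn_in=2000, retained=1000), seed=5)
        assert d.draws.shape == (1000, 6)
        assert (d.column("beta1_T") > 0).all()
        assert (d.column("beta1_E") > 0).all()
        if family == "braun":
            psi = d.column("psi")
            assert ((psi > 0) & (psi < 1)).all()
        elif family == "gumbel":
            psi = d.column("psi")
            assert ((psi > -1) & (psi < 1)).all()
        else:
            assert np.isnan(d.column("psi")).all()
        for rate in d.acceptance_rates:
            assert 0.1 <= rate <= 0.6

    def test_empty_data_rejected(self, ps1):
        with pytest.raises(ValueError):
            sample_posterior(TrialData.empty(), "independence", ps1)

    def test_empty_arm_warns(self, ps1, fast_mcmc):
        data = TrialData([1] * 6, [0, 1, 0, 0, 1, 0], [1, 0, 0, 1, 1, 0])
        with pytest.warns(UserWarning):
            sample_posterior(data, "independence", ps1, fast_mcmc, seed=0)

    def test_prior_only_recovers_prior_moments(self, ps1):
        d = sample_posterior(
            TrialData.empty(),
            "braun",
            ps1,
            MCMCConfig(burn_in=4000, retained=20000),
            seed=31,
            use_likelihood=False,
        )
        # normal prior on the toxicity intercept: N(-3, 3)
        assert d.column("beta0_T").mean() == pytest.approx(-3.0, abs=0.25)
        assert d.column("beta0_T").std() == pytest.approx(3.0, abs=0.35)
        assert d.column("beta2_E").mean() == pytest.approx(0.0, abs=0.03)
        assert d.column("beta2_E").std() == pytest.approx(0.25, abs=0.04)
        # Gamma(1/4,1/4): mean 1, sd 2; heavy tail needs loose tolerance
        assert d.column("beta1_T").mean() == pytest.approx(1.0, abs=0.3)
        # Uniform(0,1) on psi: mean 1/2, sd 1/sqrt(12)
        assert d.column("psi").mean() == pytest.approx(0.5, abs=0.05)
        assert d.column("psi").std() == pytest.approx(1.0 / math.sqrt(12.0), abs=0.03)

    def test_parameter_recovery_n2000(self, ps1, grid):
        true = MarginalParams(-2.0, 0.8, -1.2, 0.9, -0.1)
        rng = np.random.default_rng(99)
        pairs = marginal_curves(true, grid)
        z, yt, ye = [], [], []
        for lvl, pair in zip(grid.levels, pairs):
            n = 500
            z += [lvl] * n
            yt += list(rng.random(n) < pair.pi_T)
            ye += list(rng.random(n) < pair.pi_E)
        data = TrialData(np.array(z), np.array(yt, dtype=int), np.array(ye, dtype=int))
        d = sample_posterior(data, "independence", ps1, MCMCConfig(burn_in=6000, retained=4000), seed=17)
        for name, truth in [
            ("beta0_T", -2.0),
            ("beta1_T", 0.8),
            ("beta0_E", -1.2),
            ("beta1_E", 0.9),
            ("beta2_E", -0.1),
        ]:
            col = d.column(name)
            assert abs(col.mean() - truth) < 3.0 * col.std(), name

    def test_braun_fit_to_independent_data_near_half(self, ps1, grid):
        rng = np.random.default_rng(123)
        n = 1500
        z = rng.integers(1, 5, size=n)
        yt = (rng.random(n) < 0.3).astype(int)
        ye = (rng.random(n) < 0.5).astype(int)
        d = sample_posterior(TrialData(z, yt, ye), "braun", ps1, MCMCConfig(burn_in=4000, retained=2000), seed=3)
        assert d.column("psi").mean() == pytest.approx(0.5, abs=0.05)

    def test_grid_approximation_agreement(self, ps1, grid):
        """Intercepts-only toy posterior vs independent quadrature."""
        rng = np.random.default_rng(5)
        n = 30
        yt = (rng.random(n) < 0.2).astype(int)
        ye = (rng.random(n) < 0.4).astype(int)
        data = TrialData(np.ones(n, dtype=int), yt, ye)
        mask = np.array([True, False, True, False, False, False])
        init = np.array([-3.0, math.log(1e-6), -1.0, math.log(1e-6), 0.0, 0.0])
        with pytest.warns(UserWarning):
            d = sample_posterior(
                data, "independence", ps1,
                MCMCConfig(burn_in=5000, retained=30000),
                seed=11, init=init, update_mask=mask,
            )
        # quadrature oracle, one intercept at a time (posteriors factorize)
        b = np.linspace(-15, 10, 4001)
        for name, mean_prior, successes in [("beta0_T", -3.0, yt.sum()), ("beta0_E", -1.0, ye.sum())]:
            p = expit(b)
            lp = -0.5 * ((b - mean_prior) / 3.0) ** 2 + successes * np.log(p) + (n - successes) * np.log(1 - p)
            w = np.exp(lp - lp.max())
            w /= w.sum()
            assert d.column(name).mean() == pytest.approx(float(np.sum(w * b)), abs=0.02)

    def test_ess_positive(self, fixed_design_data, ps1, fast_mcmc):
        d = sample_posterior(fixed_design_data, "braun", ps1, fast_mcmc, seed=8)
        assert 1.0 <= d.ess("psi") <= d.retained


class TestPosteriorDoseSummaries:
    def _single_draw(self, family, row):
        from copulatrial.inference import PosteriorDraws

        return PosteriorDraws(
            draws=np.array([row]), family=family, burn_in=0, retained=1, seed=0, acceptance_rates=(0.3,)
        )

    def test_intercept_only_independence(self, grid):
        d = self._single_draw("independence", [-3.0, 1e-12, -1.0, 1e-12, 0.0, np.nan])
        pi_t, pi_e = posterior_dose_summaries(d, grid)
        assert pi_t[0, 0] == pytest.approx(0.04742587, abs=1e-6)
        assert pi_e[0, 0] == pytest.approx(0.26894142, abs=1e-6)

    def test_braun_half_equals_logistic(self, grid):
        row = [-2.0, 0.5, -1.0, 0.7, -0.05, 0.5]
        a = self._single_draw("braun", row)
        b = self._single_draw("independence", row)
        np.testing.assert_allclose(posterior_dose_summaries(a, grid)[0], posterior_dose_summaries(b, grid)[0], atol=1e-12)
        np.testing.assert_allclose(posterior_dose_summaries(a, grid)[1], posterior_dose_summaries(b, grid)[1], atol=1e-12)

    def test_braun_summary_matches_joint_table_sums(self, grid):
        row = [-2.0, 0.5, -1.0, 0.7, -0.05, 0.9]
        d = self._single_draw("braun", row)
        pi_t, pi_e = posterior_dose_summaries(d, grid)
        params = MarginalParams(-2.0, 0.5, -1.0, 0.7, -0.05)
        for k, pair in enumerate(marginal_curves(params, grid)):
            t = joint_table(pair, CopulaSpec("braun", 0.9))
            assert pi_t[0, k] == pytest.approx(t.p11 + t.p10, abs=1e-12)
            assert pi_e[0, k] == pytest.approx(t.p11 + t.p01, abs=1e-12)
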