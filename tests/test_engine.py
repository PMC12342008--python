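"""Sequential neural posterior estimation engine."""

import numpy as np
import pytest

from npfit import metrics
from npfit.engine import EngineConfig, EngineError, fit_patient, posterior_sample
from npfit.features import fit_normalizer, summarize
from npfit.noise import make_forward
from npfit.priors import PriorSpec, prior_from_center
from npfit.surrogate import PatientRecord, generate_cohort, simulate


def _conjugate_setup():
    """1-parameter toy: x = theta * exp(eps), lognormal prior on theta.

    The posterior over ln(theta) is Gaussian in closed form; the unused
    noise dimension keeps the parameter layout (theta, sigma).
    """
    mu0, tau, s_n = np.log(2.0), 0.5, 0.3
    prior = PriorSpec(("theta", "sigma"), np.array([mu0, np.log(0.2)]), np.array([tau, 0.25]), {})
    x_o = np.array([3.0])
    post_var = 1.0 / (1.0 / tau**2 + 1.0 / s_n**2)
    post_mean = post_var * (mu0 / tau**2 + np.log(x_o[0]) / s_n**2)

    def forward(pv, rng):
        return np.array([pv.values[0] * np.exp(rng.normal(0.0, s_n))])

    return prior, x_o, forward, np.exp(post_mean), np.sqrt(post_var)


class TestConjugateToy:
    def test_posterior_median_matches_closed_form(self):
        prior, x_o, forward, true_median, _ = _conjugate_setup()
        model, logs = fit_patient(x_o, prior, forward, EngineConfig(seed=1))
        draws = np.array([t.values[0] for t in posterior_sample(model, 2000, 7)])
        assert np.median(draws) == pytest.approx(true_median, rel=0.10)
        assert len(logs) == 10
        assert logs[0].proposal_source == "prior"
        assert all(log.proposal_source == "posterior" for log in logs[1:])

    def test_posterior_spread_is_in_the_right_regime(self):
        prior, x_o, forward, _, true_sd = _conjugate_setup()
        model, _ = fit_patient(x_o, prior, forward, EngineConfig(seed=2))
        draws = np.array([t.values[0] for t in posterior_sample(model, 2000, 8)])
        assert 0.5 * true_sd < np.std(np.log(draws)) < 2.0 * true_sd

    def test_single_round_reduces_to_plain_npe(self):
        prior, x_o, forward, true_median, _ = _conjugate_setup()
        cfg = EngineConfig(n_rounds=1, n_sims_per_round=500, max_epochs=200, patience=20, seed=3)
        model, logs = fit_patient(x_o, prior, forward, cfg)
        assert len(logs) == 1 and logs[0].proposal_source == "prior"
        draws = np.array([t.values[0] for t in posterior_sample(model, 2000, 9)])
        assert np.median(draws) == pytest.approx(true_median, rel=0.15)


@pytest.fixture(scope="module")
def toy_model():
    prior, x_o, forward, _, _ = _conjugate_setup()
    cfg = EngineConfig(n_rounds=2, n_sims_per_round=50, max_epochs=30, seed=4)
    model, _ = fit_patient(x_o, prior, forward, cfg)
    return model


class TestPosteriorSampleContract:
    def test_same_seed_gives_identical_samples(self, toy_model):
        a = posterior_sample(toy_model, 50, 11)
        b = posterior_sample(toy_model, 50, 11)
        assert all(np.array_equal(x.values, y.values) for x, y in zip(a, b))

    def test_samples_strictly_positive_and_counted(self, toy_model):
        draws = posterior_sample(toy_model, 100, 12)
        assert len(draws) == 100
        assert all(np.all(t.values > 0) for t in draws)

    def test_log_prob_finite_on_samples(self, toy_model):
        for t in posterior_sample(toy_model, 20, 13):
            assert np.isfinite(toy_model.log_prob(t))


class TestEngineOnSurrogate:
    def test_best_posterior_sample_beats_prior_median_parametrization(self, spec):
        """Noise-free observation from a theta* inside the prior bulk."""
        reference = spec.reference_param_vector()
        wins = 0
        for rep in range(3):
            rng = np.random.default_rng(200 + rep)
            shift = np.exp(rng.normal(0.0, 0.25, reference.values.size - 1))
            theta_star = reference.replace_values(np.append(reference.values[:-1] * shift, 1e-12))
            traj = simulate(theta_star, spec)
            patient = PatientRecord("t", {b: (t.copy(), v.copy()) for b, (t, v) in traj.series.items()})
            # a second synthetic patient so the normalizer has dispersion
            other = PatientRecord("o", {b: (t.copy(), v.copy() * 1.5) for b, (t, v) in traj.series.items()})
            normalizer = fit_normalizer([
                summarize(patient, spec.biomarker_names),
                summarize(other, spec.biomarker_names),
            ])
            x_o = normalizer.normalize(summarize(patient, spec.biomarker_names))
            prior = prior_from_center(reference, scale=0.25, noise_loc=0.2)
            forward = make_forward(patient, spec, normalizer)
            model, _ = fit_patient(x_o, prior, forward, EngineConfig(seed=rep))
            _, loss_best, _ = metrics.posterior_metrics(model, patient, spec, reference, n=100, seed=rep)
            loss_prior_median = metrics.loss(prior.median(), patient, spec)
            wins += loss_best < loss_prior_median
        assert wins >= 2

    def test_sequential_improvement_over_first_round(self, spec):
        """Median loss of final-round posterior samples <= first-round's."""
        reference = spec.reference_param_vector()
        patients, _ = generate_cohort(2, spec, pop_scale=0.35, seed=77)
        patient = patients[0]
        normalizer = fit_normalizer([summarize(p, spec.biomarker_names) for p in patients])
        x_o = normalizer.normalize(summarize(patient, spec.biomarker_names))
        prior = prior_from_center(reference, scale=0.25, noise_loc=0.2)
        forward = make_forward(patient, spec, normalizer)

        def median_loss(cfg):
            model, _ = fit_patient(x_o, prior, forward, cfg)
            losses = []
            for t in posterior_sample(model, 30, 5):
                try:
                    losses.append(metrics.loss(t, patient, spec))
                except Exception:
                    losses.append(np.inf)
            return np.median(losses)

        results = []
        for seed in (0, 1, 2):
            first = median_loss(EngineConfig(n_rounds=1, seed=seed))
            final = median_loss(EngineConfig(n_rounds=10, seed=seed))
            results.append(final <= first * 1.05)
        assert sum(results) >= 2

    def test_marginals_neutral_to_parameter_ordering(self, spec):
        """Permuting parameter names (prior permuted accordingly) leaves
        each marginal posterior essentially unchanged."""
        from npfit.surrogate import DEFAULT_FIT_PARAMS

        patients, _ = generate_cohort(2, spec, pop_scale=0.3, seed=55)
        patient = patients[0]
        normalizer = fit_normalizer([summarize(p, spec.biomarker_names) for p in patients])
        x_o = normalizer.normalize(summarize(patient, spec.biomarker_names))
        medians = []
        for order in (DEFAULT_FIT_PARAMS, DEFAULT_FIT_PARAMS[::-1]):
            ref = spec.reference_param_vector(order)
            prior = prior_from_center(ref, 0.25, 0.2)
            model, _ = fit_patient(x_o, prior, make_forward(patient, spec, normalizer), EngineConfig(seed=4))
            draws = np.array([t.values for t in model.sample(500, 9)])
            medians.append({n: np.median(draws[:, i]) for i, n in enumerate(ref.names)})
        for name in medians[0]:
            log_ratio = abs(np.log(medians[0][name] / medians[1][name]))
            assert log_ratio < 0.25, name  # well within one prior scale

    def test_all_invalid_simulations_abort_with_diagnostic(self):
        prior, x_o, _, _, _ = _conjugate_setup()

        def forward(pv, rng):
            return None

        with pytest.raises(EngineError, match="invalid"):
            fit_patient(x_o, prior, forward, EngineConfig(n_rounds=2, seed=0))


class TestConfigValidation:
    def test_atoms_bounded_by_simulations_per_round(self):
        with pytest.raises(ValueError):
            EngineConfig(n_sims_per_round=10, n_atoms=25)

    def test_unknown_estimator_family_rejected(self):
        with pytest.raises(ValueError):
            EngineConfig(density_estimator="nsf")
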