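import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socialdrift.accumulator import (
    AccumulatorParameters,
    FitResult,
    ModelVariant,
    PredictorSet,
    SamplerConfig,
    all_variants,
    category_probabilities,
    classify_evidence_ratio,
    compute_looic,
    evidence_ratio,
    fit_hierarchical,
    log_likelihood,
    trial_moments,
)
from socialdrift.design import DesignConfig
from socialdrift.preprocessing import apply_trial_filters
from socialdrift.synthetic import (
    PopulationSpec,
    simulate_experiment,
)
from scipy.special import ndtr

EXP1_PARAMS = AccumulatorParameters(
    delta_easy=0.90, delta_hard=0.60, delta_s=0.18, gamma=2.41, tau=0.0
)


class TestTrialMoments:
    def test_social_drift_adjustment_matches_reported_magnitude(self):
        """At delta_s = 0.18 and a judgment 3.1 s after the cue, the drift
        part of the social adjustment is 0.558, i.e. 0.56 to two decimals,
        on top of the instantaneous shift of 2.41."""
        pred = PredictorSet(dt_s=6.1, st_s=3.1, col=1, lam=1, si_present=1)
        mean, var = trial_moments(EXP1_PARAMS, pred, "easy")
        personal = 0.90 * 6.1
        social = mean - personal
        assert social == pytest.approx(0.18 * 3.1 + 2.41)
        assert round(0.18 * 3.1, 2) == 0.56
        assert var == pytest.approx(6.1)

    def test_zero_parameters(self):
        params = AccumulatorParameters(0, 0, 0, 0, 0)
        mean, var = trial_moments(params, PredictorSet(dt_s=4.0), "easy")
        assert mean == 0.0 and var == 4.0

    def test_odd_symmetry_in_col_and_validity(self):
        params = AccumulatorParameters(0.5, 0.3, 0.2, 1.5, 0.0)
        pred = PredictorSet(dt_s=5.0, st_s=2.0, col=1, lam=1, si_present=1)
        flipped = PredictorSet(dt_s=5.0, st_s=2.0, col=-1, lam=-1, si_present=1)
        m1, _ = trial_moments(params, pred, "easy")
        m2, _ = trial_moments(params, flipped, "easy")
        # personal drift is defined on the correctness axis, social terms flip
        assert m2 == pytest.approx(2 * 0.5 * 5.0 - m1)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            PredictorSet(dt_s=0.0)
        with pytest.raises(ValueError):
            PredictorSet(dt_s=2.0, st_s=3.0, lam=1, si_present=1)
        with pytest.raises(ValueError):
            trial_moments(EXP1_PARAMS, PredictorSet(dt_s=1.0), "medium")


class TestCategoryProbabilities:
    def test_symmetric_at_zero_mean(self):
        p = category_probabilities(0.0, 4.0, EXP1_PARAMS.criteria)
        assert np.allclose(p, p[::-1])

    def test_limit_all_mass_in_top_category(self):
        p = category_probabilities(1e4, 1.0, EXP1_PARAMS.criteria)
        assert p[-1] == pytest.approx(1.0)

    @settings(max_examples=200, derandomize=True)
    @given(
        mean=st.floats(-20, 20),
        var=st.floats(0.1, 50),
        incs=st.lists(st.floats(0.05, 3), min_size=5, max_size=5),
    )
    def test_normalization_property(self, mean, var, incs):
        params = AccumulatorParameters(0, 0, 0, 0, criteria_increments=tuple(incs))
        p = category_probabilities(mean, var, params.criteria)
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()

    def test_mirror_symmetry_under_colour_relabelling(self):
        """Swapping the two colours everywhere (dominant colour, colour bias)
        exactly reverses the colour-axis judgment distribution; the symmetric
        criteria make the reflection exact."""

        def colour_axis_probs(params, pred, difficulty):
            p = category_probabilities(
                *trial_moments(params, pred, difficulty), params.criteria
            )
            # correctness axis -> colour axis: identity when orange dominates
            return p if pred.col == 1 else p[::-1]

        pred = PredictorSet(dt_s=6.0, st_s=3.0, col=1, lam=1, si_present=1)
        mirrored = PredictorSet(dt_s=6.0, st_s=3.0, col=-1, lam=1, si_present=1)
        for tau in (0.0, 0.4):
            a = AccumulatorParameters(0.5, 0.0, 0.2, 1.5, tau)
            b = AccumulatorParameters(0.5, 0.0, 0.2, 1.5, -tau)
            pa = colour_axis_probs(a, pred, "easy")
            pb = colour_axis_probs(b, mirrored, "easy")
            assert np.allclose(pa, pb[::-1], atol=1e-14)

    def test_rejects_unordered_criteria(self):
        with pytest.raises(ValueError):
            category_probabilities(0.0, 1.0, np.arange(10)[::-1].astype(float))
        with pytest.raises(ValueError):
            category_probabilities(0.0, -1.0, EXP1_PARAMS.criteria)
        with pytest.raises(ValueError):
            AccumulatorParameters(0, 0, 0, 0, criteria_increments=(1, -1, 1, 1, 1))


def _tiny_dataset(params, n, seed, col=1):
    from helpers import constant_latency, flat_schedule, single_subject

    sched = flat_schedule(n, "early-correct", onset=750, validity=1, col=col)
    subj = single_subject(
        delta_easy=params.delta_easy,
        delta_s=params.delta_s,
        gamma=params.gamma,
        tau=params.tau,
    )
    from socialdrift.synthetic import simulate_dataset

    return simulate_dataset(
        sched, subj, constant_latency(), seed=seed,
        criteria_increments=params.criteria_increments,
    )


class TestLogLikelihood:
    def test_central_bin_closed_form(self):
        params = AccumulatorParameters(0, 0, 0, 0, 0)
        df = pd.DataFrame(
            {
                "subject_id": ["a"],
                "confidence_category": [6],
                "col": [1],
                "difficulty": ["easy"],
                "dt_s": [4.0],
                "st_s": [0.0],
                "si_validity": [0],
            }
        )
        total, per = log_likelihood(params, df)
        c6 = params.criteria[5]
        expected = np.log(2 * ndtr(c6 / 2.0) - 1)
        assert total == pytest.approx(expected)
        assert len(per) == 1

    def test_additivity_under_duplication(self):
        data = _tiny_dataset(EXP1_PARAMS, 200, seed=3)
        t1, _ = log_likelihood(EXP1_PARAMS, data)
        t2, _ = log_likelihood(EXP1_PARAMS, pd.concat([data, data]))
        assert t2 == pytest.approx(2 * t1)

    def test_generating_parameters_beat_perturbed_ones(self):
        """Self-consistency: across replicates the truth almost always
        scores at least as well as +-50% perturbations of each drift."""
        wins = 0
        n_rep = 100
        for rep in range(n_rep):
            data = _tiny_dataset(EXP1_PARAMS, 400, seed=1000 + rep)
            base, _ = log_likelihood(EXP1_PARAMS, data)
            ok = True
            for factor in (0.5, 1.5):
                pert = AccumulatorParameters(
                    EXP1_PARAMS.delta_easy * factor,
                    EXP1_PARAMS.delta_hard,
                    EXP1_PARAMS.delta_s * factor,
                    EXP1_PARAMS.gamma * factor,
                    EXP1_PARAMS.tau,
                )
                ll, _ = log_likelihood(pert, data)
                ok = ok and base >= ll
            wins += ok
        assert wins >= 0.95 * n_rep


def test_timing_dichotomy_closed_form():
    """delta_s = 0: early and late social information at equal DT give
    identical predicted distributions; delta_s > 0: the early-late mean
    evidence gap is exactly delta_s * (ST_early - ST_late)."""
    shift_only = AccumulatorParameters(0.5, 0.3, 0.0, 2.0, 0.1)
    early = PredictorSet(dt_s=6.0, st_s=4.25, col=1, lam=1, si_present=1)
    late = PredictorSet(dt_s=6.0, st_s=1.75, col=1, lam=1, si_present=1)
    pe = category_probabilities(*trial_moments(shift_only, early, "easy"), shift_only.criteria)
    pl = category_probabilities(*trial_moments(shift_only, late, "easy"), shift_only.criteria)
    assert np.max(np.abs(pe - pl)) < 1e-12

    with_drift = AccumulatorParameters(0.5, 0.3, 0.18, 2.0, 0.1)
    me, _ = trial_moments(with_drift, early, "easy")
    ml, _ = trial_moments(with_drift, late, "easy")
    assert me - ml == pytest.approx(0.18 * (4.25 - 1.75), abs=1e-12)


class TestEvidenceRatio:
    def test_direct_count(self):
        assert evidence_ratio(np.array([1.0, 2.0, -1.0, 3.0]), "+") == 3.0

    def test_symmetric_draws(self):
        rng = np.random.default_rng(0)
        er = evidence_ratio(rng.standard_normal(20_000), "+")
        assert 0.9 < er < 1.1

    def test_all_compatible_capped(self):
        assert evidence_ratio(np.ones(50), "+") == 50.0

    def test_errors(self):
        with pytest.raises(ValueError):
            evidence_ratio(np.array([]))
        with pytest.raises(ValueError):
            evidence_ratio(np.ones(3), "up")

    def test_conventional_classification(self):
        assert classify_evidence_ratio(2.0) == "weak"
        assert classify_evidence_ratio(10.0) == "substantial"
        assert classify_evidence_ratio(50.0) == "strong"


def test_eight_distinct_variants():
    variants = all_variants()
    assert len(variants) == 8
    assert len({v.name for v in variants}) == 8
    full = ModelVariant()
    assert full.active_mask.all()
    assert not ModelVariant(False, False, False).active_mask[:4].any()


@pytest.fixture(scope="module")
def small_fit_data():
    pop = PopulationSpec.experiment1(n_subjects=5)
    sim = simulate_experiment(pop, DesignConfig(experiment=1, seed=5), seed=17)
    return pop, apply_trial_filters(sim.dataset, "accumulation"), sim.subject_parameters


def test_fit_is_deterministic_under_seed(small_fit_data):
    _, data, _ = small_fit_data
    cfg = SamplerConfig(n_chains=2, n_iter=160, n_burn=80, seed=9, rhat_tol=10)
    f1 = fit_hierarchical(data, ModelVariant(), cfg)
    f2 = fit_hierarchical(data, ModelVariant(), cfg)
    for key in f1.draws:
        assert np.array_equal(f1.draws[key], f2.draws[key])
    assert f1.n_draws == 2 * 80


def test_fit_recovers_population_means(small_fit_data):
    pop, data, _ = small_fit_data
    cfg = SamplerConfig(n_chains=3, n_iter=900, n_burn=450, seed=2, rhat_tol=1.3)
    fit = fit_hierarchical(data, ModelVariant(), cfg)
    for name in ("delta_easy", "gamma"):
        draws = fit.population_draws(name)
        lo, hi = np.percentile(draws, [1, 99])
        assert lo < pop.means[name] < hi, name
    assert fit.n_floored == 0
    assert set(fit.rhat) == {"mu", "sigma_pop", "increments"}


def test_degenerate_hierarchy_recovers_shared_truth():
    """Two subjects drawn at zero population spread: the population mean
    must recover the (shared) generating parameters."""
    pop = PopulationSpec.experiment1(n_subjects=2)
    pop = PopulationSpec(
        means=pop.means,
        sds={k: 0.0 for k in pop.sds},
        latency=pop.latency,
        n_subjects=2,
    )
    sim = simulate_experiment(pop, DesignConfig(experiment=1, seed=8), seed=23)
    data = apply_trial_filters(sim.dataset, "accumulation")
    cfg = SamplerConfig(n_chains=3, n_iter=900, n_burn=450, seed=4, rhat_tol=2.0)
    fit = fit_hierarchical(data, ModelVariant(), cfg)
    for name in ("delta_easy", "delta_hard", "gamma"):
        draws = fit.population_draws(name)
        lo, hi = np.percentile(draws, [1, 99])
        assert lo < pop.means[name] < hi, name


def test_shift_only_data_concentrates_social_drift_near_zero():
    pop = PopulationSpec.experiment1(n_subjects=8).with_means(delta_s=0.0)
    pop = PopulationSpec(
        means=pop.means,
        sds={**pop.sds, "delta_s": 0.0},
        latency=pop.latency,
        n_subjects=8,
    )
    sim = simulate_experiment(pop, DesignConfig(experiment=1, seed=6), seed=29)
    data = apply_trial_filters(sim.dataset, "accumulation")
    fit = fit_hierarchical(
        data, ModelVariant(), SamplerConfig(n_chains=3, n_iter=900, n_burn=450, seed=3, rhat_tol=2.0)
    )
    draws = fit.population_draws("delta_s")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    assert lo < 0.0 < hi or abs(draws.mean()) < 0.08


def _fake_fit(loglik):
    """FitResult carrying only a pointwise log-likelihood matrix."""
    return FitResult(
        variant=ModelVariant(),
        draws={
            "mu": np.zeros((2, loglik.shape[1], 5)),
            "sigma_pop": np.ones((2, loglik.shape[1], 5)),
            "increments": np.ones((2, loglik.shape[1], 5)),
        },
        subject_ids=["a"],
        rhat={},
        ess={},
        log_likelihood=loglik,
        n_obs=loglik.shape[2],
        n_floored=0,
        converged=True,
        max_rhat=1.0,
        config=SamplerConfig(n_chains=2, n_iter=2, n_burn=1, seed=0),
        accept_rates={},
    )


def test_looic_scales_with_duplicated_trials():
    rng = np.random.default_rng(1)
    ll = np.log(rng.uniform(0.05, 0.4, size=(2, 200, 150)))
    single = compute_looic(_fake_fit(ll))
    doubled = compute_looic(_fake_fit(np.concatenate([ll, ll], axis=2)))
    assert doubled.looic == pytest.approx(2 * single.looic, rel=0.02)


def test_looic_of_uniform_responses_matches_analytic_value():
    """Judgments uniform over the 11 categories fitted with the bias-only
    variant: out-of-sample deviance approaches 2 * N * ln(11)."""
    rng = np.random.default_rng(5)
    n = 600
    rows = []
    for subject in ("a", "b", "c"):
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject,
                    "confidence_category": rng.integers(1, 12, n),
                    "col": rng.choice([-1, 1], n),
                    "difficulty": rng.choice(["easy", "hard"], n),
                    "dt_s": 6.0,
                    "st_s": 0.0,
                    "si_validity": 0,
                }
            )
        )
    data = pd.concat(rows, ignore_index=True)
    fit = fit_hierarchical(
        data,
        ModelVariant(False, False, False),
        SamplerConfig(n_chains=2, n_iter=500, n_burn=250, seed=7, rhat_tol=10),
    )
    loo = compute_looic(fit)
    assert loo.looic == pytest.approx(2 * len(data) * np.log(11), rel=0.02)


def test_fit_requires_two_subjects():
    df = pd.DataFrame(
        {
            "subject_id": ["a"] * 4,
            "confidence_category": [5, 6, 7, 8],
            "col": [1, 1, -1, -1],
            "difficulty": ["easy"] * 4,
            "dt_s": [6.0] * 4,
            "st_s": [0.0] * 4,
            "si_validity": [0] * 4,
        }
    )
    with pytest.raises(ValueError, match="two subjects"):
        fit_hierarchical(df, ModelVariant(), SamplerConfig(n_chains=2, n_iter=20, n_burn=10, seed=0))
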