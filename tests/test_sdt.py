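import numpy as np
import pandas as pd
import pytest

from socialdrift.accumulator import SamplerConfig
from socialdrift.sdt import (
    COEF_NAMES,
    CONDITIONS,
    SdtFitResult,
    build_design,
    dprime_contrasts,
    fit_binary_probit,
    fit_ordered_probit,
    posterior_predictive_confidence,
)
from socialdrift.preprocessing import apply_trial_filters

QUICK = SamplerConfig(n_chains=3, n_iter=1200, n_burn=600, seed=2, rhat_tol=1.3)


@pytest.fixture(scope="module")
def exp1_ordinal_fit(ordinal_dataset):
    design = build_design(ordinal_dataset)
    return design, fit_ordered_probit(design, QUICK)


def simulate_ordinal(
    dprime=1.4, n_subjects=10, n_trials=100, sigma_u=0.3, seed=0, deltas=None
):
    """Generate data directly from the ordered-probit model (independent of
    the accumulation machinery): latent = s * (d' + condition deltas) +
    subject intercept + unit noise, cut at fixed thresholds."""
    rng = np.random.default_rng(seed)
    deltas = deltas or {}
    cuts = np.linspace(-2.5, 2.5, 10)
    rows = []
    for i in range(n_subjects):
        u = sigma_u * rng.standard_normal()
        col = rng.choice([-1, 1], n_trials)
        cond = rng.choice(CONDITIONS, n_trials)
        hard = rng.choice([0, 1], n_trials)
        trial = np.arange(1, n_trials + 1)
        d_eff = dprime + np.array([deltas.get(c, 0.0) for c in cond])
        eta = (col / 2) * d_eff + u + rng.standard_normal(n_trials)
        j = np.searchsorted(cuts, eta) + 1
        treatment = np.where(cond == "absent", "no-social", cond)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": f"s{i:02d}",
                    "trial_index": trial,
                    "treatment": treatment,
                    "difficulty": np.where(hard == 1, "hard", "easy"),
                    "col": col,
                    "confidence_category": j,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestBuildDesign:
    def test_stimulus_coding_and_row_count(self, ordinal_dataset):
        one = ordinal_dataset[ordinal_dataset["subject_id"] == "s000"]
        design = build_design(one)
        assert len(design) == 100  # 120 trials minus 20 fillers
        assert set(design["condition"]) <= set(CONDITIONS)
        assert np.allclose(design["s"], design["col"] / 2)
        assert design.loc[design["col"] == 1, "s"].eq(0.5).all()
        assert design["trial_z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert np.std(design["trial_z"].to_numpy()) == pytest.approx(1.0, rel=1e-6)

    def test_filler_and_degenerate_inputs_rejected(self, exp1_simulation):
        with pytest.raises(ValueError, match="filler"):
            build_design(exp1_simulation.dataset)
        const = simulate_ordinal(n_subjects=2, n_trials=5, seed=1)
        const["trial_index"] = 7
        with pytest.raises(ValueError, match="z-scoring"):
            build_design(const)


class TestOrderedProbit:
    def test_recovers_known_dprime(self):
        data = simulate_ordinal(dprime=1.4, seed=3)
        fit = fit_ordered_probit(build_design(data), QUICK)
        draws = fit.coef_draws("dprime_baseline")
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo < 1.4 < hi
        assert abs(draws.mean() - 1.4) < 0.3

    def test_null_data_gives_zero_dprime(self):
        data = simulate_ordinal(dprime=0.0, seed=4)
        fit = fit_ordered_probit(build_design(data), QUICK)
        draws = fit.coef_draws("dprime_baseline")
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo < 0.0 < hi

    def test_accumulator_timing_pattern(self, exp1_ordinal_fit):
        """Simulation at the experiment-1 point estimates must show the
        early > late ordering for correct social information and the more
        negative early effect for wrong social information."""
        _, fit = exp1_ordinal_fit
        s = fit.summary().set_index("coefficient")["mean"]
        assert s["delta_early_correct"] > s["delta_late_correct"] > 0
        assert s["delta_early_wrong"] < s["delta_late_wrong"] < 0


def _constant_fit(value=0.0, n=400):
    beta = np.full((2, n, len(COEF_NAMES)), value)
    beta[:, :, 0] = 1.0  # baseline d' irrelevant to the condition contrasts
    return SdtFitResult(
        coef_names=COEF_NAMES,
        draws={
            "beta": beta,
            "cutpoints": np.tile(np.linspace(-2.5, 2.5, 10), (2, n, 1)),
            "sigma_u": np.full((2, n), 0.1),
            "u": np.zeros((2, n, 3)),
        },
        subject_ids=["a", "b", "c"],
        rhat={},
        ess={},
        converged=True,
        max_rhat=1.0,
        config=SamplerConfig(n_chains=2, n_iter=2 * n, n_burn=n, seed=0),
        kind="ordered-probit",
    )


class TestContrasts:
    def test_equal_condition_draws_give_null_contrasts(self):
        table = dprime_contrasts(_constant_fit()).set_index("contrast")
        for name in ("early_minus_late_correct", "early_minus_late_wrong", "timing_symmetry"):
            assert table.loc[name, "estimate"] == 0.0
        assert table.loc["delta_early_correct", "estimate"] == 0.0

    def test_contrast_table_shape(self, exp1_ordinal_fit):
        _, fit = exp1_ordinal_fit
        table = dprime_contrasts(fit)
        assert {"contrast", "estimate", "ci_lower", "ci_upper", "evidence_ratio"} <= set(
            table.columns
        )
        assert len(table) == 10
        assert (table["ci_lower"] <= table["ci_upper"]).all()

    def test_requires_ordered_probit(self):
        fit = _constant_fit()
        fit.kind = "binary-probit"
        with pytest.raises(ValueError):
            dprime_contrasts(fit)


class TestBinaryProbit:
    def test_validity_signs_at_point_estimates(self, exp1_simulation):
        data = apply_trial_filters(exp1_simulation.dataset, "accuracy")
        fit = fit_binary_probit(data, "validity", QUICK)
        s = fit.summary().set_index("coefficient")["mean"]
        assert s["si_correct"] > 0
        assert s["si_wrong"] < 0
        assert s["hard"] < 0

    def test_presence_model_runs(self, exp1_simulation):
        data = apply_trial_filters(exp1_simulation.dataset, "accuracy")
        fit = fit_binary_probit(data, "presence", QUICK)
        names = set(fit.summary()["coefficient"])
        assert "si_present" in names

    def test_null_effect_when_si_ignored(self):
        """If responses do not depend on the social cue, validity
        coefficients concentrate near zero."""
        data = simulate_ordinal(dprime=1.0, seed=6)
        data["si_validity"] = np.select(
            [data["treatment"].str.endswith("correct"), data["treatment"].str.endswith("wrong")],
            [1, -1],
            default=0,
        )
        data["late_flag"] = False
        data = data[data["confidence_category"] != 6]
        fit = fit_binary_probit(data, "validity", QUICK)
        s = fit.summary().set_index("coefficient")
        for name in ("si_correct", "si_wrong"):
            assert s.loc[name, "ci_lower"] < 0 < s.loc[name, "ci_upper"]

    def test_single_class_rejected(self):
        data = simulate_ordinal(dprime=1.0, n_subjects=2, n_trials=20, seed=7)
        data["confidence_category"] = np.where(data["col"] == 1, 11, 1)
        data["si_validity"] = 0
        data["difficulty"] = "easy"
        data["late_flag"] = False
        with pytest.raises(ValueError, match="single class"):
            fit_binary_probit(data, "validity", QUICK)
        with pytest.raises(ValueError, match="predictor"):
            fit_binary_probit(data, "both", QUICK)


class TestPosteriorPredictive:
    def test_distributions_sum_to_one_and_match_frequencies(self):
        """Self-consistency at large n: per condition, the posterior
        predictive distribution is within total-variation 0.05 of the
        frequencies simulated from the generating ordinal model."""
        deltas = {
            "early-correct": 0.9,
            "late-correct": 0.7,
            "early-wrong": -1.1,
            "late-wrong": -0.9,
        }
        data = simulate_ordinal(
            dprime=1.4, n_subjects=10, n_trials=1200, seed=9, deltas=deltas
        )
        design = build_design(data)
        fit = fit_ordered_probit(design, QUICK)
        pred = posterior_predictive_confidence(fit, design, n_draws=150, seed=1)
        probs = pred.drop(columns="condition").to_numpy()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        folded = np.where(
            design["col"] == 1,
            design["confidence_category"],
            12 - design["confidence_category"],
        )
        for row, cond in zip(probs, pred["condition"]):
            sel = folded[(design["condition"] == cond).to_numpy()]
            assert len(sel) > 1500
            emp = np.bincount(sel, minlength=12)[1:] / len(sel)
            assert 0.5 * np.abs(row - emp).sum() < 0.05, cond

    def test_early_correct_has_more_high_confidence_mass(self, exp1_ordinal_fit):
        design, fit = exp1_ordinal_fit
        pred = posterior_predictive_confidence(fit, design, n_draws=150, seed=2)
        pred = pred.set_index("condition")
        top = [f"p_cat_{j}" for j in (10, 11)]
        assert pred.loc["early-correct", top].sum() > pred.loc["late-correct", top].sum()
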