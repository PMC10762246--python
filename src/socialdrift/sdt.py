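"""Signal-detection analyses of the 11-point confidence judgments.

The ordered-probit regression treats the judgment (1 = certain blue ...
11 = certain orange) as an ordinal response cut from a latent normal with
unit noise. The stimulus is coded ``s = col/2`` (+-0.5), so the coefficient
on ``s`` is the discrimination ability d' (latent class-mean separation),
and social-information condition, stimulus difficulty and trial number
enter in interaction with ``s`` as changes in d'. Subjects contribute a
random intercept on the latent scale. A companion binary probit models
correctness directly.

Both models are fitted by the same blocked adaptive Metropolis scheme used
for the accumulation model, with conjugate-free random-walk updates and
arviz convergence diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from .accumulator import LOG_FLOOR, SamplerConfig, evidence_ratio
from .preprocessing import add_judgment_columns

CONDITIONS = ("absent", "early-correct", "late-correct", "early-wrong", "late-wrong")
COEF_NAMES = (
    "dprime_baseline",
    "delta_early_correct",
    "delta_late_correct",
    "delta_early_wrong",
    "delta_late_wrong",
    "delta_hard",
    "delta_trial",
)
_TREATMENT_TO_CONDITION = {
    "no-social": "absent",
    "early-correct": "early-correct",
    "late-correct": "late-correct",
    "early-wrong": "early-wrong",
    "late-wrong": "late-wrong",
}


def build_design(dataset: pd.DataFrame) -> pd.DataFrame:
    """Deterministic design table for the signal-detection models.

    One row per retained trial with the stimulus code ``s = col/2``, the
    five-level social-information condition, a hard-trial indicator and the
    z-scored trial number. Filler trials must have been filtered out
    beforehand; an unknown treatment or a degenerate trial-number column is
    rejected.
    """
    unknown = set(dataset["treatment"].unique()) - set(_TREATMENT_TO_CONDITION)
    if unknown:
        raise ValueError(
            f"unknown treatment labels {sorted(unknown)}; filler trials must be "
            "filtered out before building the design"
        )
    trial = dataset["trial_index"].to_numpy(float)
    if np.std(trial) == 0:
        raise ValueError("trial numbers are constant; z-scoring is undefined")
    design = pd.DataFrame(
        {
            "subject_id": dataset["subject_id"],
            "s": dataset["col"].to_numpy(float) / 2.0,
            "condition": dataset["treatment"].map(_TREATMENT_TO_CONDITION),
            "hard": (dataset["difficulty"] == "hard").astype(float),
            "trial_z": (trial - trial.mean()) / trial.std(),
            "col": dataset["col"],
            "confidence_category": dataset["confidence_category"],
        }
    ).reset_index(drop=True)
    return design


def _coef_matrix(design: pd.DataFrame) -> np.ndarray:
    s = design["s"].to_numpy(float)
    cond = design["condition"].to_numpy()
    cols = [s]
    for level in CONDITIONS[1:]:
        cols.append(s * (cond == level))
    cols.append(s * design["hard"].to_numpy(float))
    cols.append(s * design["trial_z"].to_numpy(float))
    return np.column_stack(cols)


@dataclass
class SdtFitResult:
    """Posterior draws and diagnostics of a (binary or ordinal) probit fit."""

    coef_names: tuple[str, ...]
    draws: dict[str, np.ndarray]
    subject_ids: list
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    max_rhat: float
    config: SamplerConfig
    kind: str  # "ordered-probit" or "binary-probit"

    def coef_draws(self, name: str) -> np.ndarray:
        k = self.coef_names.index(name)
        return self.draws["beta"][:, :, k].reshape(-1)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.coef_names:
            d = self.coef_draws(name)
            lo, hi = np.percentile(d, [2.5, 97.5])
            rows.append(
                {
                    "coefficient": name,
                    "mean": float(d.mean()),
                    "ci_lower": float(lo),
                    "ci_upper": float(hi),
                }
            )
        return pd.DataFrame(rows)


def _ordered_loglik(eta, cut, j0):
    cut_ext = np.concatenate([[-np.inf], cut, [np.inf]])
    p = ndtr(cut_ext[j0 + 1] - eta) - ndtr(cut_ext[j0] - eta)
    return np.log(np.maximum(p, LOG_FLOOR))


def _cuts_from_raw(raw: np.ndarray) -> np.ndarray:
    """First cutpoint plus nine positive increments; ordered by construction."""
    return raw[0] + np.concatenate([[0.0], np.cumsum(np.exp(raw[1:]))])


def _empirical_cut_init(j0: np.ndarray, n_cat: int = 11) -> np.ndarray:
    freq = np.bincount(j0, minlength=n_cat) / len(j0)
    cum = np.clip(np.cumsum(freq)[:-1], 1e-3, 1 - 1e-3)
    cuts = ndtri(cum)
    inc = np.maximum(np.diff(cuts), 0.05)
    return np.concatenate([[cuts[0]], np.log(inc)])


def _num_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; the targets here are smooth and cheap."""
    n = len(x)
    h = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            pp = x.copy(); pp[i] += eps; pp[j] += eps
            pm = x.copy(); pm[i] += eps; pm[j] -= eps
            mp = x.copy(); mp[i] -= eps; mp[j] += eps
            mm = x.copy(); mm[i] -= eps; mm[j] -= eps
            h[i, j] = h[j, i] = (f(pp) - f(pm) - f(mp) + f(mm)) / (4 * eps**2)
    return h


def _laplace_chol(f, x, fallback_scale: float = 0.05) -> np.ndarray:
    """Cholesky factor of the inverse Hessian at the optimum, used to shape
    block proposals; falls back to a diagonal if the Hessian is not PD."""
    try:
        h = _num_hessian(f, x)
        cov = np.linalg.inv(h)
        cov = (cov + cov.T) / 2
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return fallback_scale * np.eye(len(x))


def fit_ordered_probit(
    design: pd.DataFrame, config: SamplerConfig | None = None
) -> SdtFitResult:
    """Hierarchical ordered-probit regression of the 11-point judgment.

    Latent mean per trial: ``s * (d' + sum of condition/difficulty/trial
    effects) + subject intercept``; ten free ordered thresholds shared
    across subjects; unit latent noise (probit identification). Priors are
    weakly informative: N(0, 3^2) on the d' coefficients, half-normal(1) on
    the intercept spread.
    """
    config = config or SamplerConfig()
    df = design.sort_values("subject_id", kind="stable").reset_index(drop=True)
    X = _coef_matrix(df)
    j0 = df["confidence_category"].to_numpy(int) - 1
    if j0.min() < 0 or j0.max() > 10:
        raise ValueError("confidence_category must lie in 1..11")
    subjects = df["subject_id"].to_numpy()
    ids, starts = np.unique(subjects, return_index=True)
    ids = ids[np.argsort(starts)]
    bounds = np.append(np.sort(starts), len(df))
    subj_index = np.repeat(np.arange(len(ids)), np.diff(bounds))
    n_subj, n_coef = len(ids), X.shape[1]
    if n_subj < 2:
        raise ValueError("at least two subjects are required")
    coef_scale = 3.0
    sd_scale = 1.0

    # pooled (no-intercept) penalized optimum to start every chain
    raw0 = _empirical_cut_init(j0)

    def negll(v):
        beta, raw = v[:n_coef], v[n_coef:]
        ll = _ordered_loglik(X @ beta, _cuts_from_raw(raw), j0).sum()
        return -(ll - 0.5 * np.sum(beta**2) / coef_scale**2)

    res = minimize(
        negll,
        np.concatenate([np.zeros(n_coef), raw0]),
        method="L-BFGS-B",
        options={"maxiter": 300},
    )
    v_map = res.x
    chol = _laplace_chol(negll, v_map)
    n_dim = len(v_map)

    def logprior(v):
        beta, raw = v[:n_coef], v[n_coef:]
        return (
            -0.5 * np.sum(beta**2) / coef_scale**2
            - 0.5 * raw[0] ** 2 / 5.0**2
            + np.sum(-0.5 * np.exp(raw[1:]) ** 2 / 2.0**2 + raw[1:])
        )

    n_keep = (config.n_iter - config.n_burn) // config.thin
    beta_out = np.zeros((config.n_chains, n_keep, n_coef))
    cut_out = np.zeros((config.n_chains, n_keep, 10))
    sd_out = np.zeros((config.n_chains, n_keep))
    u_out = np.zeros((config.n_chains, n_keep, n_subj))

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for chain, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        v = v_map + 0.3 * chol @ rng.standard_normal(n_dim)
        beta, cuts = v[:n_coef], _cuts_from_raw(v[n_coef:])
        u = 0.1 * rng.standard_normal(n_subj)
        sigma_u = 0.3
        eta = X @ beta + u[subj_index]
        ll_subj = np.add.reduceat(_ordered_loglik(eta, cuts, j0), bounds[:-1])
        ls_v = np.log(0.6)  # scalar multiplier on the Laplace-shaped proposal
        ls_u = np.full(n_subj, np.log(0.2))

        kept = 0
        for t in range(config.n_iter):
            adapting = t < config.n_burn
            step = 1.0 / max(t, 20) ** 0.6

            # coefficients and thresholds: one Laplace-shaped joint block
            v_p = v + np.exp(ls_v) * (chol @ rng.standard_normal(n_dim))
            beta_p, cuts_p = v_p[:n_coef], _cuts_from_raw(v_p[n_coef:])
            eta_p = X @ beta_p + u[subj_index]
            ll_p = _ordered_loglik(eta_p, cuts_p, j0)
            logr = ll_p.sum() - ll_subj.sum() + logprior(v_p) - logprior(v)
            acc = np.log(rng.uniform()) < logr
            if acc:
                v, beta, cuts, eta = v_p, beta_p, cuts_p, eta_p
                ll_subj = np.add.reduceat(ll_p, bounds[:-1])
            if adapting:
                ls_v += step * (acc - 0.25)

            # subject intercepts
            for i in range(n_subj):
                lo, hi = bounds[i], bounds[i + 1]
                u_p = u[i] + np.exp(ls_u[i]) * rng.standard_normal()
                eta_i = eta[lo:hi] + (u_p - u[i])
                ll_i = _ordered_loglik(eta_i, cuts, j0[lo:hi]).sum()
                logr = (
                    ll_i
                    - ll_subj[i]
                    + 0.5 * (u[i] ** 2 - u_p**2) / sigma_u**2
                )
                acc = np.log(rng.uniform()) < logr
                if acc:
                    eta[lo:hi] = eta_i
                    ll_subj[i] = ll_i
                    u[i] = u_p
                if adapting:
                    ls_u[i] += step * (acc - 0.44)

            # intercept spread: inverse-gamma independence proposal from the
            # normal conditional; only the half-normal prior ratio remains.
            dev2 = float(np.sum(u**2))
            v_sig = max(dev2, 1e-12) / (2.0 * rng.gamma((n_subj - 1) / 2.0))
            logr = -(v_sig - sigma_u**2) / (2.0 * sd_scale**2)
            if np.log(rng.uniform()) < logr:
                sigma_u = np.sqrt(v_sig)

            if t >= config.n_burn and (t - config.n_burn) % config.thin == 0:
                beta_out[chain, kept] = beta
                cut_out[chain, kept] = cuts
                sd_out[chain, kept] = sigma_u
                u_out[chain, kept] = u
                kept += 1

    draws = {"beta": beta_out, "cutpoints": cut_out, "sigma_u": sd_out, "u": u_out}
    diag = {"beta": beta_out, "sigma_u": sd_out}
    rhat_ds = az.rhat(az.from_dict(posterior=diag))
    ess_ds = az.ess(az.from_dict(posterior=diag))
    rhat = {k: float(np.max(rhat_ds[k].values)) for k in diag}
    ess = {k: float(np.min(ess_ds[k].values)) for k in diag}
    max_rhat = max(rhat.values())
    return SdtFitResult(
        coef_names=COEF_NAMES,
        draws=draws,
        subject_ids=list(ids),
        rhat=rhat,
        ess=ess,
        converged=bool(max_rhat <= config.rhat_tol),
        max_rhat=float(max_rhat),
        config=config,
        kind="ordered-probit",
    )


def dprime_contrasts(fit: SdtFitResult) -> pd.DataFrame:
    """Directional d' contrasts with 95% intervals and evidence ratios.

    Includes each condition effect against zero, the early-late contrasts
    within correct and within wrong social information, the |correct| vs
    |wrong| magnitude comparison per timing, and the timing-symmetry
    contrast (early-late effect for correct SI minus the magnitude of the
    early-late effect for wrong SI).
    """
    if fit.kind != "ordered-probit":
        raise ValueError("contrasts require an ordered-probit fit")
    d = {name: fit.coef_draws(name) for name in COEF_NAMES}
    contrasts = {
        "dprime_baseline": (d["dprime_baseline"], "+"),
        "delta_early_correct": (d["delta_early_correct"], "+"),
        "delta_late_correct": (d["delta_late_correct"], "+"),
        "delta_early_wrong": (d["delta_early_wrong"], "-"),
        "delta_late_wrong": (d["delta_late_wrong"], "-"),
        "early_minus_late_correct": (
            d["delta_early_correct"] - d["delta_late_correct"],
            "+",
        ),
        "early_minus_late_wrong": (
            d["delta_early_wrong"] - d["delta_late_wrong"],
            "-",
        ),
        "abs_correct_minus_abs_wrong_early": (
            np.abs(d["delta_early_correct"]) - np.abs(d["delta_early_wrong"]),
            "+",
        ),
        "abs_correct_minus_abs_wrong_late": (
            np.abs(d["delta_late_correct"]) - np.abs(d["delta_late_wrong"]),
            "+",
        ),
        "timing_symmetry": (
            (d["delta_early_correct"] - d["delta_late_correct"])
            - np.abs(d["delta_early_wrong"] - d["delta_late_wrong"]),
            "+",
        ),
    }
    rows = []
    for name, (draws, direction) in contrasts.items():
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rows.append(
            {
                "contrast": name,
                "estimate": float(draws.mean()),
                "ci_lower": float(lo),
                "ci_upper": float(hi),
                "direction": direction,
                "evidence_ratio": evidence_ratio(draws, direction),
            }
        )
    return pd.DataFrame(rows)


def fit_binary_probit(
    dataset: pd.DataFrame,
    predictor: str = "validity",
    config: SamplerConfig | None = None,
) -> SdtFitResult:
    """Hierarchical probit regression of correctness.

    ``predictor='validity'`` codes correct and wrong social information
    against the no-social baseline; ``predictor='presence'`` codes any
    social information against its absence. Difficulty, stimulus colour and
    z-scored trial number are included; subjects contribute random
    intercepts. The accuracy trial filter (neutral responses and fillers
    removed) must have been applied.
    """
    if predictor not in ("validity", "presence"):
        raise ValueError("predictor must be 'validity' or 'presence'")
    config = config or SamplerConfig()
    df = add_judgment_columns(dataset).dropna(subset=["correct"])
    df = df.sort_values("subject_id", kind="stable").reset_index(drop=True)
    y = df["correct"].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("correctness has a single class; probit fit is undefined")
    trial = df["trial_index"].to_numpy(float)
    if np.std(trial) == 0:
        raise ValueError("trial numbers are constant; z-scoring is undefined")
    if predictor == "validity":
        names = ("intercept", "si_correct", "si_wrong", "hard", "col", "trial_z")
        X = np.column_stack(
            [
                np.ones(len(df)),
                (df["si_validity"] == 1).to_numpy(float),
                (df["si_validity"] == -1).to_numpy(float),
                (df["difficulty"] == "hard").to_numpy(float),
                df["col"].to_numpy(float),
                (trial - trial.mean()) / trial.std(),
            ]
        )
    else:
        names = ("intercept", "si_present", "hard", "col", "trial_z")
        X = np.column_stack(
            [
                np.ones(len(df)),
                (df["si_validity"] != 0).to_numpy(float),
                (df["difficulty"] == "hard").to_numpy(float),
                df["col"].to_numpy(float),
                (trial - trial.mean()) / trial.std(),
            ]
        )
    subjects = df["subject_id"].to_numpy()
    ids, starts = np.unique(subjects, return_index=True)
    ids = ids[np.argsort(starts)]
    bounds = np.append(np.sort(starts), len(df))
    subj_index = np.repeat(np.arange(len(ids)), np.diff(bounds))
    n_subj, n_coef = len(ids), X.shape[1]
    coef_scale = 3.0

    def bin_ll(eta, lo=None, hi=None):
        p = np.clip(ndtr(eta), 1e-12, 1 - 1e-12)
        sl = slice(lo, hi)
        return np.log(np.where(y[sl] == 1, p, 1 - p))

    def negll(beta):
        return -(bin_ll(X @ beta).sum() - 0.5 * np.sum(beta**2) / coef_scale**2)

    beta_map = minimize(
        negll, np.zeros(n_coef), method="L-BFGS-B", options={"maxiter": 200}
    ).x
    chol = _laplace_chol(negll, beta_map)

    n_keep = (config.n_iter - config.n_burn) // config.thin
    beta_out = np.zeros((config.n_chains, n_keep, n_coef))
    sd_out = np.zeros((config.n_chains, n_keep))
    u_out = np.zeros((config.n_chains, n_keep, n_subj))
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for chain, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        beta = beta_map + 0.05 * rng.standard_normal(n_coef)
        u = 0.1 * rng.standard_normal(n_subj)
        sigma_u = 0.3
        eta = X @ beta + u[subj_index]
        ll_subj = np.add.reduceat(bin_ll(eta), bounds[:-1])
        ls_beta = np.log(0.6)
        ls_u = np.full(n_subj, np.log(0.3))
        kept = 0
        for t in range(config.n_iter):
            adapting = t < config.n_burn
            step = 1.0 / max(t, 20) ** 0.6
            beta_p = beta + np.exp(ls_beta) * (chol @ rng.standard_normal(n_coef))
            eta_p = X @ beta_p + u[subj_index]
            llp = bin_ll(eta_p)
            logr = (
                llp.sum()
                - ll_subj.sum()
                + 0.5 * (np.sum(beta**2) - np.sum(beta_p**2)) / coef_scale**2
            )
            acc = np.log(rng.uniform()) < logr
            if acc:
                beta, eta = beta_p, eta_p
                ll_subj = np.add.reduceat(llp, bounds[:-1])
            if adapting:
                ls_beta += step * (acc - 0.25)
            for i in range(n_subj):
                lo, hi = bounds[i], bounds[i + 1]
                u_p = u[i] + np.exp(ls_u[i]) * rng.standard_normal()
                eta_i = eta[lo:hi] + (u_p - u[i])
                p = np.clip(ndtr(eta_i), 1e-12, 1 - 1e-12)
                ll_i = float(np.log(np.where(y[lo:hi] == 1, p, 1 - p)).sum())
                logr = ll_i - ll_subj[i] + 0.5 * (u[i] ** 2 - u_p**2) / sigma_u**2
                acc = np.log(rng.uniform()) < logr
                if acc:
                    eta[lo:hi] = eta_i
                    ll_subj[i] = ll_i
                    u[i] = u_p
                if adapting:
                    ls_u[i] += step * (acc - 0.44)
            dev2 = float(np.sum(u**2))
            v_sig = max(dev2, 1e-12) / (2.0 * rng.gamma((n_subj - 1) / 2.0))
            if np.log(rng.uniform()) < -(v_sig - sigma_u**2) / 2.0:
                sigma_u = np.sqrt(v_sig)
            if t >= config.n_burn and (t - config.n_burn) % config.thin == 0:
                beta_out[chain, kept] = beta
                sd_out[chain, kept] = sigma_u
                u_out[chain, kept] = u
                kept += 1
    draws = {"beta": beta_out, "sigma_u": sd_out, "u": u_out}
    diag = {"beta": beta_out, "sigma_u": sd_out}
    rhat_ds = az.rhat(az.from_dict(posterior=diag))
    ess_ds = az.ess(az.from_dict(posterior=diag))
    rhat = {k: float(np.max(rhat_ds[k].values)) for k in diag}
    ess = {k: float(np.min(ess_ds[k].values)) for k in diag}
    max_rhat = max(rhat.values())
    return SdtFitResult(
        coef_names=names,
        draws=draws,
        subject_ids=list(ids),
        rhat=rhat,
        ess=ess,
        converged=bool(max_rhat <= config.rhat_tol),
        max_rhat=float(max_rhat),
        config=config,
        kind="binary-probit",
    )


def posterior_predictive_confidence(
    fit: SdtFitResult, design: pd.DataFrame, n_draws: int = 200, seed: int = 0
) -> pd.DataFrame:
    """Predicted distribution over folded confidence categories per condition.

    For each trial the model's 11 colour-axis category probabilities are
    averaged over a posterior subsample and folded onto the correctness
    axis (category 1 = certain and wrong ... 11 = certain and correct, 6 =
    neutral), then averaged within condition. Rows sum to one.
    """
    if fit.kind != "ordered-probit":
        raise ValueError("posterior predictions require an ordered-probit fit")
    rng = np.random.default_rng(seed)
    beta = fit.draws["beta"].reshape(-1, fit.draws["beta"].shape[-1])
    cuts = fit.draws["cutpoints"].reshape(-1, 10)
    take = rng.choice(len(beta), size=min(n_draws, len(beta)), replace=False)
    X = _coef_matrix(design)
    col = design["col"].to_numpy(int)
    cond = design["condition"].to_numpy()
    total = {level: np.zeros(11) for level in np.unique(cond)}
    counts = {level: int((cond == level).sum()) for level in total}
    for k in take:
        eta = X @ beta[k]
        cut_ext = np.concatenate([[-np.inf], cuts[k], [np.inf]])
        cdf = ndtr(cut_ext[None, :] - eta[:, None])
        probs = np.diff(cdf, axis=1)
        folded = np.where(col[:, None] == 1, probs, probs[:, ::-1])
        for level in total:
            total[level] += folded[cond == level].sum(axis=0)
    rows = []
    for level, vec in total.items():
        vec = vec / (len(take) * counts[level])
        rows.append({"condition": level, **{f"p_cat_{j+1}": vec[j] for j in range(11)}})
    return pd.DataFrame(rows)
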