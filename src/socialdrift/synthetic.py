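"""Synthetic experiments with the statistical structure the analysis assumes.

Generates everything needed to exercise the full pipeline without any
empirical data: subject-level accumulator parameters drawn from a
population, per-subject randomized trial schedules, confidence judgments
simulated from the generative evidence model, response latencies from a
truncated log-normal, and deliberately pathological subjects for testing
the exclusion rules.

The default populations emulate the two experiments: population means at
the reported point estimates (experiment 1: delta_easy 0.90, delta_s 0.18,
gamma 2.41; experiment 2: 0.81, 0.14, 2.06), criteria roughly 1.75 evidence
units apart, and latencies calibrated so that judgments fall on average
3.1 s (experiment 1) or 3.3 s (experiment 2) after the social cue among
analysed trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .accumulator import PARAM_NAMES, AccumulatorParameters
from .design import STIMULUS_MS, DesignConfig, build_trial_schedule

DATASET_COLUMNS_EXTRA = [
    "subject_id",
    "confidence_category",
    "latency_s",
    "dt_s",
    "st_s",
    "late_flag",
]

PATHOLOGIES = (
    "always_full_confidence",
    "below_chance",
    "chronic_late",
    "miscalibrated_confidence",
)


@dataclass(frozen=True)
class LatencyModel:
    """Log-normal response latency, truncated to (0, response_window + overtime).

    Latencies above the response window occur naturally in the tail and are
    flagged late; ``extra_late_probability`` can force additional late
    trials (uniform between window and cap) when a higher late rate is
    wanted than the tail provides.
    """

    log_mu: float
    log_sigma: float
    response_window_s: float
    overtime_s: float = 1.0
    extra_late_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.log_sigma <= 0:
            raise ValueError("log_sigma must be positive")
        if not 0 <= self.extra_late_probability < 1:
            raise ValueError("extra_late_probability must lie in [0, 1)")

    @property
    def cap_s(self) -> float:
        return self.response_window_s + self.overtime_s

    @classmethod
    def calibrated(
        cls,
        mean_kept_s: float,
        response_window_s: float,
        log_sigma: float = 0.4,
        overtime_s: float = 1.0,
    ) -> "LatencyModel":
        """Choose the location so on-time latencies average ``mean_kept_s``.

        The calibration target is the conditional mean E[X | X <= window],
        matching how the analysed (non-late) trials are summarized.
        """
        a = response_window_s

        def kept_mean(mu):
            num = np.exp(mu + log_sigma**2 / 2) * ndtr(
                (np.log(a) - mu - log_sigma**2) / log_sigma
            )
            return num / ndtr((np.log(a) - mu) / log_sigma)

        mu = brentq(lambda m: kept_mean(m) - mean_kept_s, -5.0, np.log(a))
        return cls(mu, log_sigma, response_window_s, overtime_s)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        upper = ndtr((np.log(self.cap_s) - self.log_mu) / self.log_sigma)
        u = rng.uniform(0.0, upper, size=n)
        x = np.exp(self.log_mu + self.log_sigma * ndtri(u))
        if self.extra_late_probability > 0:
            force = rng.uniform(size=n) < self.extra_late_probability
            x = np.where(
                force, rng.uniform(self.response_window_s, self.cap_s, size=n), x
            )
        return x


@dataclass(frozen=True)
class PopulationSpec:
    """Population distribution of subject-level parameters plus nuisance models."""

    means: dict[str, float]
    sds: dict[str, float]
    criteria_increments: tuple[float, ...] = (0.875, 1.75, 1.75, 1.75, 1.75)
    latency: LatencyModel = field(
        default_factory=lambda: LatencyModel.calibrated(1.1, 2.0, 0.4)
    )
    n_subjects: int = 30

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if name not in self.means or name not in self.sds:
                raise ValueError(f"population spec must define mean and sd for {name}")
            if self.sds[name] < 0:
                raise ValueError("population spreads must be non-negative")
        if np.any(np.asarray(self.criteria_increments) <= 0):
            raise ValueError("criteria increments must be strictly positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")

    @classmethod
    def experiment1(cls, n_subjects: int = 30, **overrides) -> "PopulationSpec":
        kwargs = dict(
            means={
                "delta_easy": 0.90,
                "delta_hard": 0.60,
                "delta_s": 0.18,
                "gamma": 2.41,
                "tau": 0.0,
            },
            sds={
                "delta_easy": 0.15,
                "delta_hard": 0.15,
                "delta_s": 0.06,
                "gamma": 0.75,
                "tau": 0.30,
            },
            latency=LatencyModel.calibrated(1.1, 2.0, 0.4),
            n_subjects=n_subjects,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def experiment2(cls, n_subjects: int = 30, **overrides) -> "PopulationSpec":
        kwargs = dict(
            means={
                "delta_easy": 0.81,
                "delta_hard": 0.55,
                "delta_s": 0.14,
                "gamma": 2.06,
                "tau": 0.0,
            },
            sds={
                "delta_easy": 0.15,
                "delta_hard": 0.15,
                "delta_s": 0.06,
                "gamma": 0.75,
                "tau": 0.30,
            },
            latency=LatencyModel.calibrated(1.3, 3.0, 0.5),
            n_subjects=n_subjects,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def with_means(self, **means) -> "PopulationSpec":
        new = dict(self.means)
        new.update(means)
        return replace(self, means=new)


def draw_subject_parameters(pop: PopulationSpec, seed: int = 0) -> pd.DataFrame:
    """Draw one parameter set per subject from the population distributions.

    Criteria are shared across subjects and therefore not drawn here. With
    all spreads zero every subject equals the population mean exactly.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    for name in PARAM_NAMES:
        rows[name] = pop.means[name] + pop.sds[name] * rng.standard_normal(
            pop.n_subjects
        )
    out = pd.DataFrame(rows)
    out.insert(0, "subject_id", [f"s{i:03d}" for i in range(pop.n_subjects)])
    return out


def _bin_evidence(evidence: np.ndarray, criteria: np.ndarray) -> np.ndarray:
    """Map evidence values to 1..11 via the ordered criteria."""
    return np.searchsorted(criteria, evidence, side="right") + 1


def simulate_dataset(
    schedule: pd.DataFrame,
    subject_params: pd.DataFrame,
    latency: LatencyModel,
    seed: int = 0,
    criteria_increments: tuple[float, ...] = (0.875, 1.75, 1.75, 1.75, 1.75),
) -> pd.DataFrame:
    """Simulate judgments for every subject on the given trial schedule.

    Per trial, evidence is drawn from the model's normal distribution on
    the correctness axis, binned by the shared symmetric criteria, and then
    reported on the colour axis (category 1 = certain blue ... 11 = certain
    orange). Trials without social information (including fillers) zero the
    social terms. Latencies beyond the response window are flagged late but
    still receive judgments, as in the task.
    """
    rng = np.random.default_rng(seed)
    criteria = AccumulatorParameters(
        0, 0, 0, 0, criteria_increments=tuple(criteria_increments)
    ).criteria
    out = []
    n = len(schedule)
    delib_s = schedule["deliberation_ms"].to_numpy(float) / 1000.0
    col = schedule["col"].to_numpy(int)
    lam = schedule["si_validity"].to_numpy(float)
    si_present = (lam != 0).astype(float)
    onset_s = np.where(si_present == 1, schedule["si_onset_ms"].to_numpy(float) / 1000.0, 0.0)
    easy = (schedule["difficulty"] == "easy").to_numpy(float)
    rw = schedule["response_window_ms"].to_numpy(float) / 1000.0
    for _, subj in subject_params.iterrows():
        lat = latency.sample(n, rng)
        dt = STIMULUS_MS / 1000.0 + delib_s + lat
        if np.any(dt <= 0):
            raise ValueError("DT must be positive; check deliberation and latency")
        st = (delib_s - onset_s + lat) * si_present
        delta_p = np.where(easy == 1, subj["delta_easy"], subj["delta_hard"])
        mean = (
            subj["tau"] * col
            + delta_p * dt
            + (subj["delta_s"] * st + subj["gamma"]) * lam * si_present
        )
        evidence = mean + np.sqrt(dt) * rng.standard_normal(n)
        jc = _bin_evidence(evidence, criteria)
        j = np.where(col == 1, jc, 12 - jc)
        block = schedule.copy()
        block.insert(0, "subject_id", subj["subject_id"])
        block["confidence_category"] = j
        block["latency_s"] = lat
        block["dt_s"] = dt
        block["st_s"] = st
        block["late_flag"] = lat > rw
        out.append(block)
    return pd.concat(out, ignore_index=True)


@dataclass
class SimulatedExperiment:
    dataset: pd.DataFrame
    subject_parameters: pd.DataFrame
    population: PopulationSpec
    design: DesignConfig


def simulate_experiment(
    pop: PopulationSpec, design: DesignConfig, seed: int = 0
) -> SimulatedExperiment:
    """Full synthetic experiment: per-subject schedules plus judgments.

    Each subject receives an independently randomized schedule (as in the
    task, where trial order was randomized within block per participant);
    all randomness derives from ``seed``.
    """
    root = np.random.SeedSequence(seed)
    param_seed, sim_root = root.spawn(2)
    params = draw_subject_parameters(pop, seed=int(param_seed.generate_state(1)[0] % 2**31))
    datasets = []
    for i, (sched_ss, judge_ss) in enumerate(
        zip(sim_root.spawn(pop.n_subjects), np.random.SeedSequence((seed, 1)).spawn(pop.n_subjects))
    ):
        cfg = replace(design, seed=int(sched_ss.generate_state(1)[0] % 2**31))
        schedule = build_trial_schedule(cfg)
        subj = params.iloc[[i]]
        datasets.append(
            simulate_dataset(
                schedule,
                subj,
                pop.latency,
                seed=int(judge_ss.generate_state(1)[0] % 2**31),
                criteria_increments=pop.criteria_increments,
            )
        )
    return SimulatedExperiment(
        dataset=pd.concat(datasets, ignore_index=True),
        subject_parameters=params,
        population=pop,
        design=design,
    )


def inject_exclusion_pathologies(
    dataset: pd.DataFrame, spec: dict[str, str], seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overwrite named subjects' records with known exclusion-worthy behaviour.

    ``spec`` maps subject_id -> pathology, one of:

    - ``always_full_confidence``: ~95% of trials at an extreme category,
      triggering the >90% full-confidence rule;
    - ``below_chance``: reports the wrong side on most trials, pushing
      accuracy below 50%;
    - ``chronic_late``: 12 responses beyond the response window, exceeding
      the >10 late-response rule;
    - ``miscalibrated_confidence``: fully confident when wrong, lukewarm
      when correct, so mean confidence on wrong trials exceeds that on
      correct trials.

    Returns the modified dataset and a truth-label table so downstream
    exclusion tests are self-verifying. An empty spec returns the data
    unchanged.
    """
    unknown = set(spec.values()) - set(PATHOLOGIES)
    if unknown:
        raise ValueError(f"unknown pathologies: {sorted(unknown)}")
    missing = set(spec) - set(dataset["subject_id"].unique())
    if missing:
        raise ValueError(f"subjects not in dataset: {sorted(missing)}")
    df = dataset.copy()
    rng = np.random.default_rng(seed)
    for subject_id, pathology in spec.items():
        idx = df.index[df["subject_id"] == subject_id].to_numpy()
        col = df.loc[idx, "col"].to_numpy(int)
        if pathology == "always_full_confidence":
            chosen = rng.choice(idx, size=int(np.ceil(0.95 * len(idx))), replace=False)
            side = rng.choice([-1, 1], size=len(chosen))
            df.loc[chosen, "confidence_category"] = np.where(side == 1, 11, 1)
        elif pathology == "below_chance":
            chosen = rng.choice(idx, size=int(np.ceil(0.7 * len(idx))), replace=False)
            wrong_col = -df.loc[chosen, "col"].to_numpy(int)
            df.loc[chosen, "confidence_category"] = np.where(wrong_col == 1, 9, 3)
        elif pathology == "chronic_late":
            chosen = rng.choice(idx, size=12, replace=False)
            rw = df.loc[chosen, "response_window_ms"].to_numpy(float) / 1000.0
            df.loc[chosen, "latency_s"] = rw + 0.3
            df.loc[chosen, "late_flag"] = True
        elif pathology == "miscalibrated_confidence":
            wrong = rng.uniform(size=len(idx)) < 0.3
            df.loc[idx[wrong], "confidence_category"] = np.where(
                col[wrong] == 1, 1, 11
            )
            df.loc[idx[~wrong], "confidence_category"] = np.where(
                col[~wrong] == 1, 7, 5
            )
    labels = pd.DataFrame(
        {"subject_id": list(spec), "pathology": [spec[s] for s in spec]}
    )
    return df, labels
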