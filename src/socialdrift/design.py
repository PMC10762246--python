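"""Trial schedules for the timed-social-information experiments.

A session consists of 120 trials in 20 blocks of six. Four treatments show
the choice of a previous participant (the social information, SI) either
early or late in a fixed deliberation phase, and the SI is correct on 70%
of those trials by construction (28 correct vs 12 wrong trials per timing).
A fifth treatment shows no SI and a sixth consists of short "filler" trials
that keep participants attentive and are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: treatment name -> (n_trials, nominal SI onset ms after deliberation start,
#: SI validity +1/-1), with None marking treatments without social information.
TREATMENTS: dict[str, tuple[int, int | None, int | None]] = {
    "early-correct": (28, 750, +1),
    "late-correct": (28, 3250, +1),
    "early-wrong": (12, 750, -1),
    "late-wrong": (12, 3250, -1),
    "no-social": (20, None, None),
    "filler": (20, None, None),
}

DELIBERATION_MS = 4000
FILLER_DELIBERATION_MS = 1000
STIMULUS_MS = 1000

SCHEDULE_COLUMNS = [
    "trial_index",
    "block",
    "treatment",
    "difficulty",
    "col",
    "si_validity",
    "si_onset_ms",
    "si_display_ms",
    "deliberation_ms",
    "response_window_ms",
]


@dataclass(frozen=True)
class TreatmentSpec:
    """One of the six within-subject treatments."""

    name: str
    n_trials: int
    si_onset_ms: int | None = None
    si_validity: int | None = None
    deliberation_ms: int = DELIBERATION_MS

    def __post_init__(self) -> None:
        if self.n_trials not in (28, 12, 20):
            raise ValueError(f"unsupported treatment size {self.n_trials}")
        if (self.si_onset_ms is None) != (self.si_validity is None):
            raise ValueError("si_onset_ms and si_validity must be present together")

    @property
    def has_social_information(self) -> bool:
        return self.si_validity is not None


@dataclass(frozen=True)
class DesignConfig:
    """Configuration of a full trial schedule.

    ``experiment`` selects the display rule for the social cue: in
    experiment 1 the cue stays visible until the end of the deliberation
    phase, in experiment 2 it is shown for exactly 500 ms. Experiment 2
    also extends the response window from 2 s to 3 s. The proportions of
    dominant-colour pixels are metadata describing the stimuli; nothing
    downstream consumes them.
    """

    experiment: int = 1
    n_blocks: int = 20
    jitter_ms: float = 250.0
    seed: int = 0
    easy_dominant_proportion: float = 0.515
    hard_dominant_proportion: float = 0.505

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if self.n_blocks != 20:
            raise ValueError(
                "the six-treatment composition requires 20 blocks "
                f"(got {self.n_blocks}): 28/28/12/12/20/20 trials cannot be "
                "arranged as 2 early + 2 late + 1 no-social + 1 filler per "
                "block otherwise"
            )
        if not 0 <= self.jitter_ms <= 750:
            raise ValueError("jitter_ms must lie in [0, 750] to keep onsets inside the deliberation phase")

    @property
    def response_window_ms(self) -> int:
        return 2000 if self.experiment == 1 else 3000


def _balanced_cells(n_trials: int, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Difficulty x dominant-colour cells, exactly n/4 trials each, shuffled."""
    if n_trials % 4:
        raise ValueError(f"cannot balance difficulty x colour with {n_trials} trials")
    cells = [
        (diff, col)
        for diff in ("easy", "hard")
        for col in (+1, -1)
        for _ in range(n_trials // 4)
    ]
    rng.shuffle(cells)
    return cells


def build_trial_schedule(config: DesignConfig) -> pd.DataFrame:
    """Build one participant's 120-trial schedule.

    Each block holds two early-SI trials, two late-SI trials, one no-social
    trial and one filler trial, in random order; block order is sequential.
    Difficulty and dominant colour are exactly balanced within every
    treatment. The realised SI onset is the nominal onset plus continuous
    uniform jitter on +-jitter_ms. Deterministic in ``config`` (including
    the seed).
    """
    rng = np.random.default_rng(config.seed)
    n_blocks = config.n_blocks

    pools: dict[str, list[tuple[str, int]]] = {}
    for name, (n_trials, _, _) in TREATMENTS.items():
        pools[name] = _balanced_cells(n_trials, rng)

    # interleave the two validities within each timing, then deal two per block
    early = [("early-correct", c) for c in pools["early-correct"]] + [
        ("early-wrong", c) for c in pools["early-wrong"]
    ]
    late = [("late-correct", c) for c in pools["late-correct"]] + [
        ("late-wrong", c) for c in pools["late-wrong"]
    ]
    rng.shuffle(early)
    rng.shuffle(late)

    rows = []
    for b in range(n_blocks):
        block_trials = [
            early[2 * b],
            early[2 * b + 1],
            late[2 * b],
            late[2 * b + 1],
            ("no-social", pools["no-social"][b]),
            ("filler", pools["filler"][b]),
        ]
        order = rng.permutation(len(block_trials))
        for k in order:
            treatment, (difficulty, col) = block_trials[k]
            n_trials, onset, validity = TREATMENTS[treatment]
            deliberation = (
                FILLER_DELIBERATION_MS if treatment == "filler" else DELIBERATION_MS
            )
            if onset is None:
                onset_realized = np.nan
                display = np.nan
                validity_code = 0
            else:
                onset_realized = onset + rng.uniform(-config.jitter_ms, config.jitter_ms)
                validity_code = validity
                if config.experiment == 2:
                    display = 500.0
                else:
                    display = deliberation - onset_realized
            rows.append(
                {
                    "trial_index": len(rows) + 1,
                    "block": b + 1,
                    "treatment": treatment,
                    "difficulty": difficulty,
                    "col": col,
                    "si_validity": validity_code,
                    "si_onset_ms": onset_realized,
                    "si_display_ms": display,
                    "deliberation_ms": deliberation,
                    "response_window_ms": config.response_window_ms,
                }
            )
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


@dataclass
class ValidationCheck:
    name: str
    passed: bool
    observed: object
    required: object


@dataclass
class ValidationReport:
    checks: list[ValidationCheck] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[ValidationCheck]:
        return [c for c in self.checks if not c.passed]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "check": c.name,
                    "passed": c.passed,
                    "observed": str(c.observed),
                    "required": str(c.required),
                }
                for c in self.checks
            ]
        )


def validate_schedule(
    schedule: pd.DataFrame, jitter_ms: float = 250.0
) -> ValidationReport:
    """Check a schedule against every design invariant.

    Returns a report listing, per constraint, the observed and required
    values; nothing raises (except on an empty schedule), so a deliberately
    corrupted schedule produces a readable list of failures.
    """
    if schedule.empty:
        raise ValueError("schedule is empty")
    report = ValidationReport()

    def add(name, passed, observed, required):
        report.checks.append(ValidationCheck(name, bool(passed), observed, required))

    add("total-trials", len(schedule) == 120, len(schedule), 120)

    counts = schedule["treatment"].value_counts().to_dict()
    expected = {name: spec[0] for name, spec in TREATMENTS.items()}
    add("treatment-counts", counts == expected, counts, expected)

    comp_ok = True
    observed_comp = {}
    for block, grp in schedule.groupby("block"):
        early = grp["treatment"].str.startswith("early").sum()
        late = grp["treatment"].str.startswith("late").sum()
        nosoc = (grp["treatment"] == "no-social").sum()
        filler = (grp["treatment"] == "filler").sum()
        observed_comp[int(block)] = (int(early), int(late), int(nosoc), int(filler))
        if (early, late, nosoc, filler) != (2, 2, 1, 1):
            comp_ok = False
    add(
        "block-composition",
        comp_ok,
        {b: v for b, v in observed_comp.items() if v != (2, 2, 1, 1)} or "all (2,2,1,1)",
        "(2 early, 2 late, 1 no-social, 1 filler) per block",
    )

    si = schedule[schedule["si_validity"] != 0]
    if len(si):
        accuracy = (si["si_validity"] == 1).mean()
        add("si-accuracy", np.isclose(accuracy, 0.70), round(float(accuracy), 4), 0.70)
        for timing in ("early", "late"):
            sub = si[si["treatment"].str.startswith(timing)]
            acc_t = (sub["si_validity"] == 1).mean() if len(sub) else np.nan
            add(
                f"si-accuracy-{timing}",
                np.isclose(acc_t, 0.70),
                round(float(acc_t), 4),
                0.70,
            )
        nominal = si["treatment"].str.startswith("early").map({True: 750, False: 3250})
        dev = (si["si_onset_ms"] - nominal).abs()
        add(
            "jitter-bounds",
            bool((dev <= jitter_ms + 1e-9).all()),
            round(float(dev.max()), 2),
            f"<= {jitter_ms}",
        )
    else:
        add("si-accuracy", False, "no SI trials", 0.70)

    balance_ok = True
    bad_cells = {}
    for name, (n_trials, _, _) in TREATMENTS.items():
        grp = schedule[schedule["treatment"] == name]
        cells = grp.groupby(["difficulty", "col"]).size()
        want = n_trials // 4
        if len(cells) != 4 or not (cells == want).all():
            balance_ok = False
            bad_cells[name] = cells.to_dict()
    add(
        "difficulty-colour-balance",
        balance_ok,
        bad_cells or "balanced",
        "n/4 trials per difficulty x colour cell in each treatment",
    )

    filler = schedule[schedule["treatment"] == "filler"]
    add(
        "filler-deliberation",
        bool((filler["deliberation_ms"] == FILLER_DELIBERATION_MS).all()),
        sorted(filler["deliberation_ms"].unique().tolist()),
        FILLER_DELIBERATION_MS,
    )
    return report
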