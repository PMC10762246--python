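"""Small builders shared across test modules."""

import numpy as np
import pandas as pd

from socialdrift.synthetic import LatencyModel


def constant_latency(value=1.0, window=2.0):
    # vanishing log-sd makes the decision time effectively deterministic
    return LatencyModel(np.log(value), 1e-9, window)


def flat_schedule(n, treatment="no-social", onset=None, validity=0, col=1,
                  difficulty="easy", deliberation=4000):
    """n identical trials of one treatment, for targeted simulations."""
    return pd.DataFrame(
        {
            "trial_index": np.arange(1, n + 1),
            "block": 1,
            "treatment": treatment,
            "difficulty": difficulty,
            "col": col,
            "si_validity": validity,
            "si_onset_ms": onset if onset is not None else np.nan,
            "si_display_ms": np.nan,
            "deliberation_ms": deliberation,
            "response_window_ms": 2000,
        }
    )


def single_subject(**params):
    base = dict(delta_easy=0.0, delta_hard=0.0, delta_s=0.0, gamma=0.0, tau=0.0)
    base.update(params)
    return pd.DataFrame([{"subject_id": "s0", **base}])
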