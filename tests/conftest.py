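import numpy as np
import pytest

from saccadometry.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete cohort: both groups, both tasks,
    AS errors, measurement noise."""
    cfg = SimulationConfig(n_pd=4, n_control=4, trials_per_task=12, seed=7)
    trajectories, truth = simulate_cohort(cfg)
    return cfg, trajectories, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def truth_to_saccade_table(truth):
    """Saccade-level metric table from the generator's ground-truth frame
    (damping from the drawn per-trial sigma; no trajectory fits needed)."""
    table = truth.rename(columns={"sigma": "sigma"}).copy()
    table["fit_kept"] = True
    return table[
        [
            "participant_id",
            "group",
            "task",
            "trial_index",
            "response_type",
            "latency_ms",
            "amplitude_deg",
            "peak_velocity_deg_s",
            "sigma",
            "fit_kept",
        ]
    ]
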