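import numpy as np
import pandas as pd
import pytest

import schemacells as sc


@pytest.fixture(scope="session")
def design():
    return sc.make_default_design()


@pytest.fixture(scope="session")
def session_trials(design):
    return sc.generate_session(design, seed=123)


@pytest.fixture(scope="session")
def flat_unit_matrices(design, session_trials):
    """Both-maze matrices of a flat 5-Hz Poisson unit."""
    spec = sc.TuningSpec("flat", baseline_rate=5.0)
    st = sc.generate_spikes(session_trials, spec, design, seed=7)
    return (sc.build_epoch_matrix(st, session_trials, design, "maze1"),
            sc.build_epoch_matrix(st, session_trials, design, "maze2"))


@pytest.fixture(scope="session")
def tuned_unit_matrices(design, session_trials):
    """Both-maze matrices of a strongly tuned, fully generalizing unit."""
    rng = np.random.default_rng(11)
    spec = sc.make_tuned_spec(rng, "tuned", gamma=1.0, design=design)
    st = sc.generate_spikes(session_trials, spec, design, rng)
    return (sc.build_epoch_matrix(st, session_trials, design, "maze1"),
            sc.build_epoch_matrix(st, session_trials, design, "maze2"),
            spec)


def task_labels(trials_per_type=20):
    """Label frame with the pinned trial-type ordering of a full maze."""
    rows = []
    for sub in "ab":
        for pos in ("P1", "P2", "P3", "P4"):
            for i in range(trials_per_type):
                rows.append({
                    "type_key": sub + pos, "subsequence": sub, "position": pos,
                    "rewarded": int(pos in ("P3", "P4")),
                    "within_type_index": i + 1,
                })
    return pd.DataFrame(rows)


def labelled_matrix(fn, trials_per_type=20, unit_id="u", maze_id="maze1"):
    """Deterministic EpochRateMatrix with rates fn(label_row, epoch_index)."""
    labels = task_labels(trials_per_type)
    values = np.array([[fn(row, e) for e in range(9)]
                       for _, row in labels.iterrows()], dtype=float)
    return sc.EpochRateMatrix(unit_id, maze_id, values, labels)
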