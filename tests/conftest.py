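import warnings

import numpy as np
import pandas as pd
import pytest

from eegfatigue.constants import CHANNELS, FEATURE_NAMES, TASK_CONTEXT, TASK_EVENTS

warnings.filterwarnings("ignore", category=FutureWarning)

#: Desk-scale schedule: one 10-s window per event, so every pipeline
#: stage still sees all six events at a fraction of the compute.
DESK_DURATIONS = {"s1": 10, "m1": 10, "s2": 10, "m2": 10, "s3": 10, "m3": 10}


@pytest.fixture(scope="session")
def desk_durations():
    return dict(DESK_DURATIONS)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_feature_frame(subjects, sessions=(1, 2, 3), channels=CHANNELS,
                       events=("s1", "m1", "s2", "m2", "s3", "m3"), seed=0):
    """Random-valued feature table with the real key structure."""
    gen = np.random.default_rng(seed)
    rows = []
    for subject in subjects:
        for session in sessions:
            for channel in channels:
                for event in events:
                    row = {"subject": subject, "session": session,
                           "channel": channel, "event": event}
                    row.update(dict(zip(FEATURE_NAMES, gen.normal(size=len(FEATURE_NAMES)))))
                    rows.append(row)
    return pd.DataFrame(rows)


def make_modelling_frame(n_subjects=6, sessions=(1, 2, 3), channels=CHANNELS,
                         seed=0, separation=0.0, positive_rate=0.3):
    """Labelled modelling table with optional class separation injected
    into every feature (separation=0 gives pure-noise features)."""
    gen = np.random.default_rng(seed)
    cols = [f"{ch}_{name}" for ch in channels for name in FEATURE_NAMES]
    rows = []
    for i in range(n_subjects):
        subject = f"sub{i + 1:02d}"
        for session in sessions:
            for event in TASK_EVENTS:
                label = int(gen.random() < positive_rate)
                feats = gen.normal(size=len(cols)) + separation * label
                row = {"subject": subject, "session": session,
                       "task_event": event, "context": TASK_CONTEXT[event],
                       "score": 50.0 * label, "label": label}
                row.update(dict(zip(cols, feats)))
                rows.append(row)
    frame = pd.DataFrame(rows)
    # guarantee both classes exist
    if frame["label"].nunique() < 2:
        frame.loc[frame.index[0], "label"] = 1 - frame.loc[frame.index[0], "label"]
    return frame


@pytest.fixture(scope="session")
def small_cohort(desk_durations):
    """5-subject desk-scale cohort with informative TP9+AF7."""
    from eegfatigue.synthetic import default_plans, generate_cohort

    return generate_cohort(
        n_subjects=5,
        plans=default_plans(event_durations=desk_durations),
        master_seed=42,
        informative_channels=("TP9", "AF7"),
        uninformative_gain=0.0,
        complementary=True,
        gain_bimodal=True,
        gain_physical_range=(0.6, 2.6),
        gain_mental_range=(0.6, 2.6),
        noise_scale=0.1,
    )


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    """Representative feature vectors for every event of the small cohort."""
    from eegfatigue.features import extract_feature_table

    return extract_feature_table(small_cohort.iter_recordings())


@pytest.fixture(scope="session")
def small_modelling_table(small_cohort, small_feature_table):
    """Real end-to-end modelling table for the small cohort."""
    from eegfatigue.labelling import build_modelling_table, derive_policy

    policy = derive_policy(small_cohort.scores)
    table = build_modelling_table(small_feature_table, small_cohort.scores, policy)
    assert table["label"].nunique() == 2, "fixture cohort must have both classes"
    return table
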