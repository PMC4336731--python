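import numpy as np
import pandas as pd
import pytest

import stentstrat as ss


@pytest.fixture(scope="session")
def catalog():
    return ss.FeatureCatalog.default()


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,733-record heterogeneous synthetic cohort (default study scale)."""
    cfg = ss.default_heterogeneous_config()
    frame, truth = ss.generate_cohort(cfg, seed=11)
    return frame, truth, cfg


@pytest.fixture(scope="session")
def trained_cascade(small_cohort):
    """A cascade trained on the first 2,000 records of the small cohort."""
    frame, _, _ = small_cohort
    train = frame.iloc[:2000]
    test = frame.iloc[2000:]
    cascade = ss.train_cascade(train, ("angio_restenosis_6m", "hazard_1y"))
    return cascade, train, test


def make_flat_cohort(
    n,
    n_events,
    treatment="BMS",
    endpoint="angio_restenosis_6m",
    feature_names=("bmi", "crp"),
    seed=0,
    event_scores=None,
):
    """Hand-constructible complete-case cohort frame for filter/selection tests.

    All records are >60/male/non-diabetic unless features say otherwise; the
    given endpoint has exactly ``n_events`` events.
    """
    rng = np.random.default_rng(seed)
    cat = ss.FeatureCatalog.default()
    frame = pd.DataFrame(
        {
            "record_id": [f"x{i}" for i in range(n)],
            "patient_id": [f"x{i}" for i in range(n)],
            "age": 65.0,
            "sex": "male",
            "diabetes": "no",
            "era_tag": "era1",
            "treatment": treatment,
            "three_vessel": "no",
            "followed_up": True,
        }
    )
    for ep in ss.ENDPOINTS:
        frame[ep] = "no_event"
    labels = np.array(["event"] * n_events + ["no_event"] * (n - n_events), dtype=object)
    frame[endpoint] = labels
    for name in cat.features:
        kind = cat.kind(name)
        if kind == "continuous":
            frame[name] = rng.standard_normal(n)
        elif kind == "binary":
            frame[name] = (rng.random(n) < 0.5).astype(float)
        else:
            frame[name] = rng.choice(cat.levels(name), size=n)
    return frame
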