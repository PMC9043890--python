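import numpy as np
import pandas as pd
import pytest

import proval as pv


@pytest.fixture(scope="session")
def schema():
    return pv.default_schema()


@pytest.fixture(scope="session")
def cohort():
    """Registry-sized synthetic cohort (n=147 baseline)."""
    return pv.generate_cohort(pv.default_config(), seed=11)


@pytest.fixture(scope="session")
def big_cohort():
    """Large synthetic cohort for parameter-recovery checks."""
    return pv.generate_cohort(pv.default_config(n_baseline=5000), seed=7)


@pytest.fixture(scope="session")
def big_change_table(big_cohort):
    scores = pv.score_cohort(big_cohort)
    return pv.build_change_table(scores, big_cohort)


def make_cohort_frame(schema, participants, fill=2.0):
    """Minimal well-formed cohort frame: one baseline (+ optional followup)
    row per participant spec dict."""
    rows = []
    for spec in participants:
        row = {"participant_id": spec["pid"], "visit": spec.get("visit", "baseline")}
        for item in schema.item_ids:
            row[item] = spec.get("items", {}).get(item, spec.get("fill", fill))
        row.update({k: v for k, v in spec.items()
                    if k not in ("pid", "visit", "items", "fill")})
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_frame(schema):
    return make_cohort_frame(schema, [
        {"pid": "a", "visit": "baseline", "sarcf": 4, "sppb": 6, "sex": "female",
         "age_years": 75, "followup_mode": "telephone"},
        {"pid": "a", "visit": "followup", "anchor_fitness": "about the same",
         "sarcf": 4, "followup_mode": "telephone"},
        {"pid": "b", "visit": "baseline", "sarcf": 5, "sppb": 8, "sex": "male",
         "age_years": 80, "followup_mode": "telephone"},
        {"pid": "b", "visit": "followup", "anchor_fitness": "better",
         "sarcf": 3, "followup_mode": "telephone"},
    ])


def moment_sample(mean, sd, n):
    """A sample with *exactly* the requested mean and (n-1)-denominator SD."""
    z = np.arange(n, dtype=float)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z
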