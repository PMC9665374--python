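"""Shared fixtures: desk-scale synthetic records and cohorts.

Full-length acquisitions (3.5 min at 8 kHz) are only generated where a
test needs the study-scale beat count; everything else runs on short
acquisitions, which keeps the whole suite fast while exercising the
identical code paths.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pulsewave.features import featurize_cohort
from pulsewave.synthetic import (CohortConfig, SignalConfig, SubjectRecord,
                                 generate_cohort, generate_cohort_signals,
                                 generate_signals, stratum_of)

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_subject(lvedp: float, subject_id: str = "S0", **kw) -> SubjectRecord:
    defaults = dict(age=60.0, gender="female", bmi=32.0, ef=60.0,
                    cad_obstructive=False, site_id="site01")
    defaults.update(kw)
    return SubjectRecord(subject_id=subject_id, lvedp=lvedp,
                         stratum=stratum_of(lvedp), **defaults)


@pytest.fixture(scope="session")
def fast_signal_config() -> SignalConfig:
    return SignalConfig(duration=12.0)


@pytest.fixture(scope="session")
def clean_record(fast_signal_config):
    """A 30 s elevated-LVEDP acquisition used across QC/feature tests."""
    subj = make_subject(30.0)
    return generate_signals(subj, SignalConfig(duration=30.0), seed=11)


@pytest.fixture(scope="session")
def full_length_record():
    """One study-scale (3.5 min) acquisition with 8 ms atrial jitter."""
    cfg = SignalConfig()  # defaults: 210 s
    subj = make_subject(30.0)   # elevated -> jitter SD = 2 + 6 = 8 ms
    return cfg, generate_signals(subj, cfg, seed=7)


@pytest.fixture(scope="session")
def modeling_cohort():
    """n=120 cohort (half normal, half elevated LVEDP) with features,
    generated under the default (strong) effect links."""
    cohort_cfg = CohortConfig(stratum_proportions=(0.5, 0.0, 0.5))
    subjects = generate_cohort(120, cohort_cfg, seed=21)
    records = generate_cohort_signals(
        subjects, SignalConfig(duration=12.0), seed=22)
    feats = featurize_cohort(records)
    import pandas as pd
    subj_df = pd.DataFrame([{
        "subject_id": s.subject_id, "age": s.age, "gender": s.gender,
        "bmi": s.bmi, "ef": s.ef, "lvedp": s.lvedp, "stratum": s.stratum,
        "cad_obstructive": s.cad_obstructive, "site_id": s.site_id,
    } for s in subjects]).set_index("subject_id")
    return subj_df, feats
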