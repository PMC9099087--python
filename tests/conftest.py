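import dataclasses

import hypothesis
import numpy as np
import pytest

import trialcea as tc

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=60
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def valueset():
    return tc.jp_tto()


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny deterministic synthetic cohort (8 + 8 patients)."""
    cfg = tc.default_config(seed=42)
    cfg = dataclasses.replace(
        cfg, arms={a: dataclasses.replace(ac, n=8) for a, ac in cfg.arms.items()}
    )
    return tc.generate_cohort(cfg)


def make_record(
    patient_id="P-1",
    arm="SH",
    grade="III",
    outcome="cured",
    cost=1500.0,
    eq5d_code="11111",
    hss=1,
    wexner=0,
    vas=1.0,
):
    """Minimal valid PatientRecord with constant responses across visits."""
    from trialcea.trial_data import EQ5D_VISITS, HSS_VISITS, VAS_VISITS, WEXNER_VISITS

    return tc.PatientRecord(
        patient_id=patient_id,
        arm=arm,
        grade=grade,
        outcome6m=outcome,
        total_cost=cost,
        eq5d_responses={v: tc.EQ5DState.from_code(eq5d_code) for v in EQ5D_VISITS},
        hss={v: hss for v in HSS_VISITS},
        wexner={v: wexner for v in WEXNER_VISITS},
        vas={v: vas for v in VAS_VISITS},
    )
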