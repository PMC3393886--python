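"""CPP session generator: schedule validation, bounds, calibration, determinism."""

import numpy as np
import pytest

from cppherit import (
    ALL_SAL_SCHEDULE,
    CPPDesign,
    PROTOCOL_SCHEDULE,
    GeneticParams,
    InvalidScheduleError,
    derive_phenotypes,
    simulate_cpp_sessions,
)
from cppherit.cpp import MA_DAYS, REST_DAYS, TEST_DAYS

from conftest import ACTIVITY, REWARD


def test_protocol_schedule_layout():
    assert all(PROTOCOL_SCHEDULE[d] == "MA" for d in MA_DAYS)
    assert all(PROTOCOL_SCHEDULE[d] == "none" for d in REST_DAYS)
    assert all(PROTOCOL_SCHEDULE[d] == "SAL" for d in TEST_DAYS)
    assert not CPPDesign().is_control
    assert CPPDesign(schedule=dict(ALL_SAL_SCHEDULE)).is_control


@pytest.mark.parametrize(
    "patch",
    [
        {3: "MA"},  # MA on a saline training day
        {6: "SAL"},  # treatment on a rest day
        {2: "SAL", 4: "MA"},  # mixed training block
        {15: "MA"},  # drug on a test day
    ],
)
def test_inconsistent_schedules_rejected(patch):
    sched = dict(PROTOCOL_SCHEDULE)
    sched.update(patch)
    with pytest.raises(InvalidScheduleError):
        CPPDesign(schedule=sched)


def test_times_and_distances_within_bounds(study):
    s = study["sessions"]
    t = s["time_drug_side"].dropna()
    assert ((t >= 0) & (t <= study["design"].session_length)).all()
    assert (s["distance"] >= 0).all()
    # preference recorded exactly on test days
    has_time = s[s["time_drug_side"].notna()]["day"].unique()
    assert sorted(has_time) == [1, 8, 15]


def test_degenerate_noise_gives_exact_gain(small_ail):
    from cppherit import sample_study_cohort

    ped, cohort = sample_study_cohort(small_ail, 4, (4, 6), seed=3)
    design = CPPDesign(
        cpp_gain_mean=150.0, cpp_gain_sd=0.0, pref_noise_sd=0.0, initial_bias=(0.03, 0.03)
    )
    sess = simulate_cpp_sessions(design, REWARD, ACTIVITY, ped, cohort, seed=5)
    ph = derive_phenotypes(sess)
    np.testing.assert_allclose(ph["D8_minus_D1"], 150.0)
    np.testing.assert_allclose(ph["D15_CPP"], ph["D8_CPP"])  # gain equal on D8/D15


def test_all_sal_control_has_no_conditioning(small_ail):
    from cppherit import sample_study_cohort

    ped, cohort = sample_study_cohort(
        small_ail, 6, (6, 9), seed=7, distinct_parent_families=False
    )
    design = CPPDesign(schedule=dict(ALL_SAL_SCHEDULE))
    sess = simulate_cpp_sessions(design, REWARD, ACTIVITY, ped, cohort, seed=9)
    ph = derive_phenotypes(sess)
    n = len(ph)
    noise_se = np.sqrt(2) * design.pref_noise_sd / np.sqrt(n)
    assert abs(ph["D8_minus_D1"].mean()) < 4 * noise_se


def test_default_calibration_hits_reported_gain_range(study):
    mean_gain = study["phenotypes"]["D8_minus_D1"].mean()
    assert 100.0 <= mean_gain <= 250.0


def test_heritable_gain_clusters_by_family(small_ail):
    from scipy import stats as sps

    from cppherit import sample_study_cohort

    ped, cohort = sample_study_cohort(
        small_ail, 16, (10, 10), seed=11, distinct_parent_families=False
    )
    design = CPPDesign(cpp_gain_sd=100.0, pref_noise_sd=30.0)
    sess = simulate_cpp_sessions(
        design, GeneticParams(0, 0.8, 0.2), ACTIVITY, ped, cohort, seed=13
    )
    ph = derive_phenotypes(sess)
    ph = ph[ph.role == "offspring"]
    groups = [g["D8_minus_D1"].to_numpy() for _, g in ph.groupby("family_id")]
    f, p = sps.f_oneway(*groups)
    assert p < 0.01  # between-family variance detectable


def test_ma_days_more_active_than_sal_days(study):
    s = study["sessions"]
    ma = s[s.treatment == "MA"]["distance"].mean()
    sal = s[(s.treatment == "SAL") & (~s.day.isin([1, 8, 15]))]["distance"].mean()
    assert ma > 1.5 * sal


def test_bit_identical_given_seed(study):
    again = simulate_cpp_sessions(
        study["design"], REWARD, ACTIVITY, study["pedigree"], study["cohort"], seed=103
    )
    assert again.equals(study["sessions"])
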