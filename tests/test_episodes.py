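"""Eligibility, episode construction (gap rule) and OME dosing."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from opiclaims.episodes import (
    build_episode,
    build_episodes,
    build_patient_episode,
    day_grid_episode_end,
    episode_ome,
    select_eligible,
)

from conftest import d, make_bundle


def rx_frame(rows):
    """rows: (start_iso, days_supplied[, drug_code, daily_dose_mg])"""
    return pd.DataFrame(
        [
            {
                "patient_id": "A",
                "drug_code": r[2] if len(r) > 2 else "MOR_OR",
                "start_date": d(r[0]),
                "days_supplied": r[1],
                "daily_dose_mg": r[3] if len(r) > 3 else 30.0,
                "n_units": 1,
            }
            for r in rows
        ]
    )


# -- eligibility -------------------------------------------------------------


def test_opioid_before_diagnosis_only_is_not_eligible():
    b = make_bundle(
        patients=[("A", "male", 1950, "2015-01-01")],
        diagnoses=[("A", "C50", "2010-06-01")],
        prescriptions=[("A", "MOR_OR", "2010-01-01", 14, 30.0)],
    )
    assert select_eligible(b) == []


@pytest.mark.parametrize("followup,expected", [(729, 0), (730, 1)])
def test_followup_boundary_730_days(followup, expected):
    index = d("2010-01-01")
    b = make_bundle(
        patients=[("A", "male", 1950, (index + dt.timedelta(days=followup)).isoformat())],
        diagnoses=[("A", "C50", "2010-01-01")],
        prescriptions=[("A", "MOR_OR", "2010-01-01", 14, 30.0)],
    )
    assert len(select_eligible(b)) == expected


def test_index_date_is_first_opioid_on_or_after_diagnosis():
    b = make_bundle(
        patients=[("A", "male", 1950, "2015-01-01")],
        diagnoses=[("A", "C50", "2010-01-01")],
        prescriptions=[
            ("A", "NSAID", "2010-01-01", 14, 400.0),  # non-opioid never indexes
            ("A", "MOR_OR", "2010-01-01", 14, 30.0),
        ],
    )
    (e,) = select_eligible(b)
    assert e.index_date == e.first_cancer_dx_date == d("2010-01-01")


# -- episode gap rule --------------------------------------------------------


def test_29_uncovered_days_continue_episode():
    rx = rx_frame([("2010-01-01", 14), ("2010-02-13", 10)])  # uncovered 15th..43rd day = 29 d
    ep = build_episode(rx, d("2010-01-01"))
    assert ep.end_date == d("2010-02-22")
    assert ep.duration_days == 53


def test_30_uncovered_days_end_episode():
    rx = rx_frame([("2010-01-01", 14), ("2010-02-14", 10)])  # 30 uncovered days
    ep = build_episode(rx, d("2010-01-01"))
    assert ep.end_date == d("2010-01-14")
    assert ep.duration_days == 14


def test_opioid_switch_with_overlap_is_one_episode():
    rx = rx_frame([("2010-01-01", 30, "OXY_OR", 40.0), ("2010-01-20", 41, "FEN_TTS", 0.6)])
    ep = build_episode(rx, d("2010-01-01"))
    assert ep.duration_days == 60


def test_no_prescription_on_index_date_is_fatal():
    rx = rx_frame([("2010-01-05", 14)])
    with pytest.raises(ValueError, match="index date"):
        build_episode(rx, d("2010-01-01"))


def test_death_caps_episode_end():
    b = make_bundle(
        patients=[("A", "male", 1950, "2012-01-10")],
        diagnoses=[("A", "C50", "2010-01-01")],
        prescriptions=[("A", "MOR_OR", "2010-01-01", 14, 30.0)],
    )
    (e,) = select_eligible(b)
    assert build_patient_episode(b, e).end_date == d("2010-01-14")
    # now the last prescription would overrun the end of data
    b2 = make_bundle(
        patients=[("A", "male", 1950, "2012-01-10")],
        diagnoses=[("A", "C50", "2010-01-01")],
        prescriptions=[("A", "MOR_OR", "2010-01-01", 800, 30.0)],
    )
    (e2,) = select_eligible(b2)
    assert build_patient_episode(b2, e2).end_date == d("2012-01-10")


# -- OME ---------------------------------------------------------------------

OME = {"MOR_OR": 1.0, "OXY_OR": 1.5, "FEN_BUC": None, "MOR_IR": 1.0}


def test_morphine_identity_factor():
    rx = rx_frame([("2010-01-01", 10)])
    ep = episode_ome(rx, OME, build_episode(rx, d("2010-01-01")))
    assert ep.total_ome_mg == pytest.approx(300.0)
    assert ep.mean_daily_ome == pytest.approx(30.0)
    assert ep.dose_calculable


def test_oxycodone_with_covered_gap_denominator():
    # 40 mg/day x 15 d at factor 1.5 = 900 mg; a 0-mg prescription extends
    # the episode to 30 days, so the mean divides by 30.
    rx = rx_frame([("2010-01-01", 15, "OXY_OR", 40.0), ("2010-01-16", 15, "MOR_OR", 0.0)])
    ep = episode_ome(rx, OME, build_episode(rx, d("2010-01-01")))
    assert ep.duration_days == 30
    assert ep.total_ome_mg == pytest.approx(900.0)
    assert ep.mean_daily_ome == pytest.approx(30.0)


def test_non_convertible_only_episode_has_no_dose():
    rx = rx_frame([("2010-01-01", 10, "FEN_BUC", 0.8)])
    ep = episode_ome(rx, OME, build_episode(rx, d("2010-01-01")))
    assert not ep.dose_calculable
    assert ep.total_ome_mg == 0.0


def test_non_convertible_does_not_poison_mixed_sum():
    rx = rx_frame([("2010-01-01", 10, "MOR_OR", 30.0), ("2010-01-03", 2, "FEN_BUC", 0.8)])
    ep = episode_ome(rx, OME, build_episode(rx, d("2010-01-01")))
    assert ep.dose_calculable
    assert ep.total_ome_mg == pytest.approx(300.0)


def test_negative_dose_is_fatal():
    rx = rx_frame([("2010-01-01", 10, "MOR_OR", -5.0)])
    with pytest.raises(ValueError, match="negative"):
        episode_ome(rx, OME, build_episode(rx, d("2010-01-01")))


# -- properties --------------------------------------------------------------

interval_sets = st.lists(
    st.tuples(st.integers(0, 200), st.integers(1, 40)), min_size=1, max_size=12
)


@st.composite
def prescription_sets(draw):
    offs = draw(interval_sets)
    offs[0] = (0, offs[0][1])  # ensure coverage on the index day
    return offs


@given(prescription_sets())
@settings(max_examples=300, deadline=None)
def test_interval_merge_agrees_with_day_grid_oracle(offsets):
    base = d("2010-01-01")
    rx = rx_frame([((base + dt.timedelta(days=o)).isoformat(), n) for o, n in offsets])
    ep = build_episode(rx, base)
    ivs = [(base.toordinal() + o, base.toordinal() + o + n - 1) for o, n in offsets]
    assert ep.end_date.toordinal() == day_grid_episode_end(ivs, base.toordinal())


@given(prescription_sets())
@settings(max_examples=200, deadline=None)
def test_idempotence_and_translation_invariance(offsets):
    base = d("2010-01-01")
    rx = rx_frame([((base + dt.timedelta(days=o)).isoformat(), n) for o, n in offsets])
    ep = build_episode(rx, base)
    # idempotence: rebuilding from the episode's own prescriptions
    inside = rx[rx["start_date"] <= ep.end_date]
    assert build_episode(inside, base).end_date == ep.end_date
    # translation by 37 days
    rx2 = rx.assign(start_date=rx["start_date"] + dt.timedelta(days=37))
    ep2 = build_episode(rx2, base + dt.timedelta(days=37))
    assert (ep2.end_date - ep.end_date).days == 37


@given(prescription_sets(), st.integers(0, 29))
@settings(max_examples=200, deadline=None)
def test_adding_prescription_within_29_days_never_shortens(offsets, extra_gap):
    base = d("2010-01-01")
    rx = rx_frame([((base + dt.timedelta(days=o)).isoformat(), n) for o, n in offsets])
    ep = build_episode(rx, base)
    new_start = ep.end_date + dt.timedelta(days=extra_gap + 1)  # <= 29 uncovered days
    rx2 = pd.concat([rx, rx_frame([(new_start.isoformat(), 5)])], ignore_index=True)
    ep2 = build_episode(rx2, base)
    assert ep2.duration_days >= ep.duration_days


def test_batch_builder_matches_per_patient(tiny_bundle):
    eligibles = select_eligible(tiny_bundle)
    fast = build_episodes(tiny_bundle, eligibles)
    for e in eligibles:
        slow = build_patient_episode(tiny_bundle, e)
        f = fast[e.patient_id]
        assert f.end_date == slow.end_date
        assert f.total_ome_mg == pytest.approx(slow.total_ome_mg)
        assert f.dose_calculable == slow.dose_calculable
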