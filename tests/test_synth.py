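"""Synthetic-claims generator: determinism, construction guarantees, prevalences."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from opiclaims.claims import write_bundle
from opiclaims.synth import SimulationConfig, generate_bundle


def zero_gap_config(**kw):
    """All-contiguous episodes, base opioid only (no rescue dispensings)."""
    defaults = dict(
        gap_prob=0.0,
        status_probs={0: (0.0, 1.0), 1: (0.0, 1.0), 2: (0.0, 1.0)},
        nonconvertible_frac=0.0,
        post_episode_rx_prob=0.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_empty_generation():
    bundle, truth = generate_bundle(SimulationConfig(n_patients=0))
    assert bundle.n_patients == 0 and len(truth.frame) == 0


def test_seed_determinism(tmp_path):
    b1, _ = generate_bundle(SimulationConfig(n_patients=25, seed=1))
    b2, _ = generate_bundle(SimulationConfig(n_patients=25, seed=1))
    b3, _ = generate_bundle(SimulationConfig(n_patients=25, seed=2))
    write_bundle(b1, tmp_path / "a")
    write_bundle(b2, tmp_path / "b")
    for name in ("patients.csv", "diagnoses.csv", "prescriptions.csv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
    assert not b1.prescriptions.equals(b3.prescriptions)


def test_patient_streams_stable_under_n_changes():
    small, _ = generate_bundle(SimulationConfig(n_patients=5, seed=3))
    large, _ = generate_bundle(SimulationConfig(n_patients=10, seed=3))
    a = small.prescriptions.sort_values(["patient_id", "start_date", "drug_code"])
    b = large.prescriptions[large.prescriptions["patient_id"].isin(set(small.patients["patient_id"]))]
    b = b.sort_values(["patient_id", "start_date", "drug_code"])
    pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))


def test_zero_gap_episodes_are_contiguous_blocks():
    bundle, truth = generate_bundle(zero_gap_config(n_patients=60, seed=5))
    opioid_codes = {c for c in bundle.dictionary if bundle.dictionary.is_opioid(c)}
    for pid, grp in bundle.prescriptions.groupby("patient_id"):
        row = truth.frame.set_index("patient_id").loc[pid]
        grp = grp[grp["drug_code"].isin(opioid_codes)].sort_values("start_date")
        covered = 0
        prev_end = None
        for _, r in grp.iterrows():
            if prev_end is not None:
                assert r["start_date"] == prev_end + dt.timedelta(days=1)
            prev_end = r["start_date"] + dt.timedelta(days=int(r["days_supplied"]) - 1)
            covered += int(r["days_supplied"])
        assert covered == row["duration_days"]
        assert prev_end == row["end_date"]


def test_within_episode_gaps_below_persistence_window():
    bundle, truth = generate_bundle(
        SimulationConfig(n_patients=80, seed=6, post_episode_rx_prob=0.0)
    )
    info = truth.frame.set_index("patient_id")
    for pid, grp in bundle.prescriptions.groupby("patient_id"):
        opioids = grp[grp["drug_code"].isin(("MOR_OR", "MOR_IR", "FEN_BUC"))]
        ivs = sorted(
            (r["start_date"], r["start_date"] + dt.timedelta(days=int(r["days_supplied"]) - 1))
            for _, r in opioids.iterrows()
        )
        end = ivs[0][1]
        for lo, hi in ivs[1:]:
            assert (lo - end).days - 1 < 30
            end = max(end, hi)
        assert end == info.loc[pid, "end_date"]


def test_covariate_prevalences_converge():
    prev = {"back_pain": 0.45, "dur_gabapentinoid": 0.12}
    cfg = SimulationConfig(
        n_patients=2000,
        seed=11,
        covariate_prevalences=prev,
        true_betas={"back_pain": 0.3},
    )
    _, truth = generate_bundle(cfg)
    for name, p in prev.items():
        phat = truth.frame[name].mean()
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 2000, p) / 2000
        assert lo <= phat <= hi


def test_group_draw_follows_proportional_odds_model():
    cfg = SimulationConfig(
        n_patients=4000,
        seed=12,
        covariate_prevalences={"back_pain": 0.5},
        true_betas={"back_pain": 1.0},
        true_intercepts=(-1.0, -2.0),
        long_low_frac=0.0,
        nonconvertible_frac=0.0,
    )
    _, truth = generate_bundle(cfg)
    tf = truth.frame
    from scipy.special import expit

    for flag in (0, 1):
        sub = tf[tf["back_pain"] == flag]
        assert (sub["true_group"] >= 1).mean() == pytest.approx(
            expit(-1.0 + flag), abs=0.04
        )


def test_infeasible_calendar_is_fatal():
    with pytest.raises(ValueError, match="infeasible"):
        SimulationConfig(
            calendar_start=dt.date(2010, 1, 1), calendar_end=dt.date(2011, 1, 1)
        ).validate()
    with pytest.raises(ValueError, match="decreasing"):
        SimulationConfig(true_intercepts=(-2.0, -1.0)).validate()
    with pytest.raises(ValueError, match="prevalence"):
        SimulationConfig(covariate_prevalences={"back_pain": 1.4}).validate()


def test_ground_truth_consistent_with_bundle():
    bundle, truth = generate_bundle(SimulationConfig(n_patients=50, seed=13))
    tf = truth.frame
    assert set(tf["patient_id"]) == set(bundle.patients["patient_id"])
    labelled = truth.labelled
    assert set(labelled["true_group"].unique()) <= {0, 1, 2}
    # duration bands by construction
    assert (labelled.loc[labelled["true_group"] == 0, "duration_days"] < 183).all()
    case = labelled[labelled["true_group"] >= 1]
    assert (case["duration_days"] >= 183).all()
    assert (case["mean_daily_ome"] >= 120).all()
    assert (
        case.loc[case["true_group"] == 2, "duration_days"] >= 730
    ).all()
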