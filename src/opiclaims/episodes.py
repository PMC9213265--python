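"""Eligibility selection, prescription-episode construction and OME dosing.

The exposure unit of the analysis is the *prescription episode*: the
maximal run of opioid coverage anchored at the index date (first opioid
prescription on/after the first cancer diagnosis) in which no uncovered
stretch reaches the persistence gap (30 days by default).  Switching
between opioids or adding opioids never breaks an episode: coverage is
the union over all opioid prescriptions, base and rescue alike.

Gap convention: uncovered days are counted strictly between coverage
intervals (end-of-coverage to next start, the standard persistence-window
convention); an uncovered run of *exactly* ``gap_days`` days terminates
the episode ("30 days or more"), a run of ``gap_days - 1`` does not.

Dosing: the mean daily dose is the total oral-morphine-equivalent (OME)
milligrams dispensed during the episode divided by the episode duration
in days (covered-gap days included in the denominator).  Drugs with no
guideline conversion factor (fentanyl sublingual/buccal tablets,
methadone) contribute zero milligrams without invalidating the sum; the
dose is non-calculable only when the episode contains no convertible
opioid at all.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .claims import ClaimsBundle, OPIOID_ROLES, NOT_CONVERTIBLE

__all__ = [
    "EligiblePatient",
    "Episode",
    "select_eligible",
    "build_episode",
    "episode_ome",
    "build_patient_episode",
]

#: Minimum follow-up (days from index date to end of data) for eligibility.
MIN_FOLLOWUP_DAYS = 730

#: Uncovered-day run that terminates an episode.
DEFAULT_GAP_DAYS = 30


@dataclass(frozen=True)
class EligiblePatient:
    patient_id: str
    first_cancer_dx_date: _dt.date
    index_date: _dt.date
    followup_days: int  # days from index_date to end_of_data


@dataclass(frozen=True)
class Episode:
    patient_id: str
    index_date: _dt.date
    end_date: _dt.date  # last day covered by the last prescription of the episode
    total_ome_mg: float = 0.0
    mean_daily_ome: float = 0.0
    dose_calculable: bool = False

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.index_date).days + 1


def select_eligible(
    bundle: ClaimsBundle,
    cancer_prefixes: Sequence[str] | None = None,
    opioid_roles: Sequence[str] = OPIOID_ROLES,
    min_followup_days: int = MIN_FOLLOWUP_DAYS,
) -> list[EligiblePatient]:
    """Select patients meeting all three eligibility criteria.

    (i) at least one cancer diagnosis, (ii) at least one oral/transdermal
    opioid prescription on or after the first cancer diagnosis (the index
    date), and (iii) at least ``min_followup_days`` days between the index
    date and the end of the patient's data (death or last record).
    Injectable and non-listed preparations are not in the drug dictionary's
    opioid roles and therefore never qualify as index prescriptions.
    """
    if cancer_prefixes is None:
        cancer_prefixes = bundle.code_map.cancer_prefixes
    if not len(cancer_prefixes):
        raise ValueError("cancer_prefixes must be non-empty")

    dx = bundle.diagnoses
    is_cancer = dx["icd10_code"].astype(str).str.startswith(tuple(cancer_prefixes))
    first_dx = (
        dx.loc[is_cancer].groupby("patient_id")["date"].min()
        if len(dx)
        else pd.Series(dtype=object)
    )

    rx = bundle.prescriptions
    opioid_codes = {
        c for c in bundle.dictionary if bundle.dictionary.role_of(c) in opioid_roles
    }
    orx = rx[rx["drug_code"].isin(opioid_codes)].copy()
    if orx.empty or first_dx.empty:
        return []
    orx["dx_date"] = orx["patient_id"].map(first_dx)
    orx = orx[orx["dx_date"].notna()]
    orx = orx[orx["start_date"] >= orx["dx_date"]]
    index_dates = orx.groupby("patient_id")["start_date"].min()

    eod = bundle.patients.set_index("patient_id")["end_of_data"]
    out: list[EligiblePatient] = []
    for pid, index_date in index_dates.items():
        followup = (eod[pid] - index_date).days
        if followup >= min_followup_days:
            out.append(EligiblePatient(pid, first_dx[pid], index_date, followup))
    out.sort(key=lambda e: e.patient_id)
    return out


def _coverage_intervals(rx: pd.DataFrame) -> list[tuple[int, int]]:
    """Sorted, merged coverage intervals as day ordinals (closed)."""
    ivs = sorted(
        (
            (s.toordinal(), s.toordinal() + int(d) - 1)
            for s, d in zip(rx["start_date"], rx["days_supplied"])
        )
    )
    merged: list[tuple[int, int]] = []
    for lo, hi in ivs:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def build_episode(
    prescriptions: pd.DataFrame,
    index_date: _dt.date,
    gap_days: int = DEFAULT_GAP_DAYS,
    end_of_data: _dt.date | None = None,
) -> Episode:
    """Construct the index-anchored prescription episode.

    ``prescriptions`` are one patient's opioid prescriptions (any role);
    rows starting before ``index_date`` are ignored.  The episode ends on
    the last covered day before the first uncovered run of ``gap_days``
    or more (or on the last covered day overall), capped at
    ``end_of_data`` when the patient dies or is censored mid-coverage.
    Order-independent and idempotent.
    """
    rx = prescriptions[prescriptions["start_date"] >= index_date]
    if rx.empty or rx["start_date"].min() != index_date:
        raise ValueError(f"no prescription on index date {index_date}")
    blocks = _coverage_intervals(rx)
    end = blocks[0][1]
    for lo, hi in blocks[1:]:
        uncovered = lo - end - 1
        if uncovered >= gap_days:
            break
        end = max(end, hi)
    end_date = _dt.date.fromordinal(end)
    if end_of_data is not None and end_of_data < end_date:
        end_date = end_of_data
    pid = str(rx["patient_id"].iloc[0]) if "patient_id" in rx.columns else ""
    return Episode(pid, index_date, end_date)


def episode_ome(
    prescriptions: pd.DataFrame,
    ome_table: Mapping[str, float | None],
    episode: Episode,
) -> Episode:
    """Attach total and mean daily OME to an episode.

    Sums ``daily_dose_mg x ome_factor x days_supplied`` over convertible
    opioid prescriptions starting within the episode.  NOT_CONVERTIBLE
    drugs contribute zero; ``dose_calculable`` is False only when no
    convertible opioid prescription exists in the episode.
    """
    if (prescriptions["daily_dose_mg"] < 0).any():
        raise ValueError("negative daily_dose_mg in episode prescriptions")
    in_ep = prescriptions[
        (prescriptions["start_date"] >= episode.index_date)
        & (prescriptions["start_date"] <= episode.end_date)
        & prescriptions["drug_code"].isin(ome_table)
    ]
    total = 0.0
    calculable = False
    for _, row in in_ep.iterrows():
        factor = ome_table[row["drug_code"]]
        if factor is NOT_CONVERTIBLE:
            continue
        calculable = True
        total += float(row["daily_dose_mg"]) * factor * int(row["days_supplied"])
    mean = total / episode.duration_days if calculable else 0.0
    return replace(
        episode, total_ome_mg=total, mean_daily_ome=mean, dose_calculable=calculable
    )


def build_patient_episode(
    bundle: ClaimsBundle,
    eligible: EligiblePatient,
    gap_days: int = DEFAULT_GAP_DAYS,
    rx: pd.DataFrame | None = None,
) -> Episode:
    """Episode with OME for one eligible patient, straight from the bundle.

    ``rx`` may pass the patient's pre-extracted prescription rows to
    avoid a full-table scan per patient.
    """
    if rx is None:
        rx = bundle.prescriptions_for(eligible.patient_id)
    opioid_rx = rx[rx["drug_code"].map(
        lambda c: bundle.dictionary.role_of(c) in OPIOID_ROLES
    )]
    eod = bundle.patients.set_index("patient_id")["end_of_data"][eligible.patient_id]
    ep = build_episode(opioid_rx, eligible.index_date, gap_days, end_of_data=eod)
    return episode_ome(opioid_rx, bundle.dictionary.ome_table(), ep)


def build_episodes(
    bundle: ClaimsBundle,
    eligibles: Sequence[EligiblePatient],
    gap_days: int = DEFAULT_GAP_DAYS,
) -> dict[str, Episode]:
    """Batch equivalent of :func:`build_patient_episode` for a whole cohort.

    One sorted pass over the opioid prescriptions; per patient it applies
    the same end-to-start gap scan and OME sum as the per-patient
    functions (kept in agreement by tests).
    """
    rx = bundle.prescriptions
    roles = {c: info.role for c, info in bundle.dictionary.items()}
    ome = bundle.dictionary.ome_table()
    is_op = rx["drug_code"].map(lambda c: roles[c] in OPIOID_ROLES).to_numpy(bool)
    orx = rx.loc[is_op]

    pid = orx["patient_id"].to_numpy()
    start = np.fromiter((d.toordinal() for d in orx["start_date"]), np.int64, len(orx))
    days = orx["days_supplied"].to_numpy(np.int64)
    contrib = np.fromiter(
        (
            np.nan if ome[c] is NOT_CONVERTIBLE else float(d) * ome[c] * int(n)
            for c, d, n in zip(orx["drug_code"], orx["daily_dose_mg"], orx["days_supplied"])
        ),
        float,
        len(orx),
    )
    order = np.lexsort((start, pid))
    pid, start, days, contrib = pid[order], start[order], days[order], contrib[order]
    uniq, first_idx = np.unique(pid, return_index=True)
    bounds = dict(zip(uniq, zip(first_idx, np.append(first_idx[1:], len(pid)))))
    eod = bundle.patients.set_index("patient_id")["end_of_data"]

    out: dict[str, Episode] = {}
    for e in eligibles:
        lo, hi = bounds[e.patient_id]
        s, d, c = start[lo:hi], days[lo:hi], contrib[lo:hi]
        idx_ord = e.index_date.toordinal()
        keep = s >= idx_ord
        s, d, c = s[keep], d[keep], c[keep]
        cur_end = s[0] + d[0] - 1
        n = len(s)
        i = 1
        while i < n:
            if s[i] - cur_end - 1 >= gap_days:
                break
            e2 = s[i] + d[i] - 1
            if e2 > cur_end:
                cur_end = e2
            i += 1
        end_ord = min(cur_end, eod[e.patient_id].toordinal())
        vals = c[s <= end_ord]
        calculable = bool(np.any(~np.isnan(vals)))
        total = float(np.nansum(vals)) if calculable else 0.0
        ep = Episode(
            e.patient_id,
            e.index_date,
            _dt.date.fromordinal(end_ord),
            total_ome_mg=total,
            mean_daily_ome=0.0,
            dose_calculable=calculable,
        )
        out[e.patient_id] = replace(
            ep, mean_daily_ome=total / ep.duration_days if calculable else 0.0
        )
    return out


def day_grid_episode_end(
    intervals: Iterable[tuple[int, int]], index_day: int, gap_days: int = DEFAULT_GAP_DAYS
) -> int:
    """Brute-force oracle: mark every covered day on a grid and scan.

    Returns the last covered day before the first uncovered run of
    ``gap_days`` or more at/after ``index_day``.  Exists for testing the
    interval-merge builder; O(total span) rather than O(n log n).
    """
    ivs = [(lo, hi) for lo, hi in intervals if lo >= index_day]
    if not ivs or min(lo for lo, _ in ivs) != index_day:
        raise ValueError("no coverage starting on index day")
    last = max(hi for _, hi in ivs)
    grid = np.zeros(last - index_day + 1, dtype=bool)
    for lo, hi in ivs:
        grid[lo - index_day : hi - index_day + 1] = True
    run = 0
    end = index_day
    for offset, covered in enumerate(grid):
        if covered:
            run = 0
            end = index_day + offset
        else:
            run += 1
            if run >= gap_days:
                break
    return end
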