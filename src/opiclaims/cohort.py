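"""Ordinal cohort classification and the analysis covariate table.

Patients are allocated to an ordered three-level outcome:

* control (0)  — episode shorter than 183 days (any dose);
* case I  (1)  — episode >= 183 days at mean >= 120 mg/day OME, < 730 days;
* case II (2)  — episode >= 730 days at mean >= 120 mg/day OME.

Long episodes below the dose cut are excluded (``long_low_dose``), as are
patients whose episode contains no convertible opioid
(``dose_not_calculable``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .claims import ClaimsBundle
from .episodes import EligiblePatient, Episode
from .manyone import dunnett_test, steel_test

__all__ = [
    "Thresholds",
    "CohortLabel",
    "GROUP_NAMES",
    "classify",
    "extract_covariates",
    "covariate_table",
    "descriptive_table",
    "format_pct",
]

GROUP_NAMES = {0: "control", 1: "case_I", 2: "case_II"}

#: Drug-class flags evaluated before and during the episode.
DRUG_CLASS_FLAGS = (
    "non_opioid_analgesic",
    "TCA",
    "SSRI",
    "SNRI",
    "gabapentinoid",
    "antiepileptic",
    "antiarrhythmic",
    "NMDA_antagonist",
    "central_muscle_relaxant",
)


@dataclass(frozen=True)
class Thresholds:
    """Classification cut-offs (days, mg/day OME, days)."""

    long_days: int = 183
    high_dose_mg: float = 120.0
    very_long_days: int = 730
    gap_days: int = 30

    def __post_init__(self) -> None:
        if min(self.long_days, self.very_long_days, self.gap_days) < 1 or self.high_dose_mg < 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class CohortLabel:
    group: int | None  # 0/1/2, or None when excluded
    excluded_reason: str | None = None  # "long_low_dose" | "dose_not_calculable"

    @property
    def retained(self) -> bool:
        return self.group is not None


def classify(episode: Episode, thresholds: Thresholds = Thresholds()) -> CohortLabel:
    """Deterministic ordinal classification of one episode."""
    if not episode.dose_calculable:
        return CohortLabel(None, "dose_not_calculable")
    d = episode.duration_days
    if d < thresholds.long_days:
        return CohortLabel(0)
    if episode.mean_daily_ome < thresholds.high_dose_mg:
        return CohortLabel(None, "long_low_dose")
    return CohortLabel(1 if d < thresholds.very_long_days else 2)


def _flag_columns(code_map) -> dict[str, tuple[str, ...]]:
    cols: dict[str, tuple[str, ...]] = {}
    for section in (code_map.cancer_sites, code_map.metastasis, code_map.comorbidities):
        cols.update(section)
    return cols


def extract_covariates(
    bundle: ClaimsBundle,
    eligible: EligiblePatient,
    episode: Episode,
    label: CohortLabel,
    dx: pd.DataFrame | None = None,
    rx: pd.DataFrame | None = None,
    patient: pd.Series | None = None,
) -> dict:
    """One analysis-ready row for a classified patient.

    Diagnosis-based flags (cancer sites, metastasis, comorbidities) are
    true on any matching record.  Drug-class and treatment flags are
    windowed: ``pre_`` = strictly before the index date, ``dur_`` = from
    index date through episode end inclusive.  ``dx``/``rx``/``patient``
    may pass pre-extracted per-patient rows.
    """
    pat = (
        patient
        if patient is not None
        else bundle.patients.set_index("patient_id").loc[eligible.patient_id]
    )
    if dx is None:
        dx = bundle.diagnoses_for(eligible.patient_id)
    if rx is None:
        rx = bundle.prescriptions_for(eligible.patient_id)
    cm = bundle.code_map

    row: dict = {
        "patient_id": eligible.patient_id,
        "group": label.group,
        "excluded_reason": label.excluded_reason,
        "sex": pat["sex"],
        "male": int(pat["sex"] == "male"),
        "age_at_index": eligible.index_date.year - int(pat["birth_year"]),
        "days_dx_to_index": (eligible.index_date - eligible.first_cancer_dx_date).days,
        "duration_days": episode.duration_days,
        "mean_daily_ome": episode.mean_daily_ome,
        "total_ome_mg": episode.total_ome_mg,
    }

    codes = dx["icd10_code"].astype(str)
    for name, prefixes in _flag_columns(cm).items():
        row[name] = int(codes.str.startswith(prefixes).any())

    pre_dx = dx[dx["date"] < eligible.index_date]
    dur_dx = dx[(dx["date"] >= eligible.index_date) & (dx["date"] <= episode.end_date)]
    for name, tcodes in cm.treatments.items():
        row[f"pre_{name}"] = int(
            pre_dx["icd10_code"].astype(str).str.startswith(tuple(tcodes)).any()
        )
        row[f"dur_{name}"] = int(
            dur_dx["icd10_code"].astype(str).str.startswith(tuple(tcodes)).any()
        )

    roles = rx["drug_code"].map(lambda c: bundle.dictionary.role_of(c))
    pre = rx["start_date"] < eligible.index_date
    dur = (rx["start_date"] >= eligible.index_date) & (rx["start_date"] <= episode.end_date)
    for cls in DRUG_CLASS_FLAGS:
        row[f"pre_{cls}"] = int((pre & (roles == cls)).any())
        row[f"dur_{cls}"] = int((dur & (roles == cls)).any())
    return row


def covariate_table(
    bundle: ClaimsBundle,
    eligibles: list[EligiblePatient],
    episodes: dict[str, Episode],
    labels: dict[str, CohortLabel],
) -> pd.DataFrame:
    """Covariate rows for every classified patient, retained or excluded."""
    kept = [e for e in eligibles if e.patient_id in episodes]
    if not kept:
        return pd.DataFrame()
    ids = [e.patient_id for e in kept]
    pat = bundle.patients.set_index("patient_id")
    cm = bundle.code_map

    base = pd.DataFrame({"patient_id": ids})
    base["group"] = [labels[p].group for p in ids]
    base["excluded_reason"] = [labels[p].excluded_reason for p in ids]
    base["sex"] = base["patient_id"].map(pat["sex"])
    base["male"] = (base["sex"] == "male").astype(int)
    birth = base["patient_id"].map(pat["birth_year"]).astype(int)
    base["age_at_index"] = [e.index_date.year for e in kept] - birth
    base["days_dx_to_index"] = [
        (e.index_date - e.first_cancer_dx_date).days for e in kept
    ]
    base["duration_days"] = [episodes[p].duration_days for p in ids]
    base["mean_daily_ome"] = [episodes[p].mean_daily_ome for p in ids]
    base["total_ome_mg"] = [episodes[p].total_ome_mg for p in ids]

    idset = set(ids)
    index_by = {p: episodes[p].index_date for p in ids}
    end_by = {p: episodes[p].end_date for p in ids}

    dx = bundle.diagnoses[bundle.diagnoses["patient_id"].isin(idset)]
    dx_codes = dx["icd10_code"].astype(str)
    for name, prefixes in _flag_columns(cm).items():
        pos = set(dx.loc[dx_codes.str.startswith(prefixes), "patient_id"])
        base[name] = base["patient_id"].isin(pos).astype(int)

    dx_index = dx["patient_id"].map(index_by)
    dx_end = dx["patient_id"].map(end_by)
    dx_pre = dx["date"] < dx_index if len(dx) else pd.Series(dtype=bool)
    dx_dur = (
        (dx["date"] >= dx_index) & (dx["date"] <= dx_end) if len(dx) else pd.Series(dtype=bool)
    )
    for name, tcodes in cm.treatments.items():
        hit = dx_codes.str.startswith(tuple(tcodes))
        base[f"pre_{name}"] = base["patient_id"].isin(
            set(dx.loc[hit & dx_pre, "patient_id"])
        ).astype(int)
        base[f"dur_{name}"] = base["patient_id"].isin(
            set(dx.loc[hit & dx_dur, "patient_id"])
        ).astype(int)

    rx = bundle.prescriptions[bundle.prescriptions["patient_id"].isin(idset)]
    role_map = {c: info.role for c, info in bundle.dictionary.items()}
    rx_roles = rx["drug_code"].map(role_map)
    rx_index = rx["patient_id"].map(index_by)
    rx_end = rx["patient_id"].map(end_by)
    rx_pre = rx["start_date"] < rx_index if len(rx) else pd.Series(dtype=bool)
    rx_dur = (
        (rx["start_date"] >= rx_index) & (rx["start_date"] <= rx_end)
        if len(rx)
        else pd.Series(dtype=bool)
    )
    for cls in DRUG_CLASS_FLAGS:
        hit = rx_roles == cls
        base[f"pre_{cls}"] = base["patient_id"].isin(
            set(rx.loc[hit & rx_pre, "patient_id"])
        ).astype(int)
        base[f"dur_{cls}"] = base["patient_id"].isin(
            set(rx.loc[hit & rx_dur, "patient_id"])
        ).astype(int)
    return base


# ---------------------------------------------------------------------------
# Descriptive table (Table-1 shape)
# ---------------------------------------------------------------------------


def format_pct(n: int, d: int, decimals: int = 1) -> float:
    """Percentage with half-up rounding (table style); 0.0 when d == 0."""
    if d == 0:
        return 0.0
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(n) * 100 / Decimal(d)).quantize(q, rounding=ROUND_HALF_UP))


def descriptive_table(
    rows: pd.DataFrame,
    continuous: tuple[str, ...] = ("age_at_index", "days_dx_to_index", "mean_daily_ome"),
    categorical: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-factor group summaries with many-to-one p-values.

    Continuous factors: mean (SD) per group, Dunnett test of each case
    group against control.  Categorical (0/1) factors: n (%) per group,
    Steel test.  With a single group present only the descriptive columns
    are produced (p-values NaN).
    """
    kept = rows[rows["group"].notna()].copy()
    if kept.empty:
        raise ValueError("no classified patients")
    kept["group"] = kept["group"].astype(int)
    groups_present = sorted(kept["group"].unique())
    if categorical is None:
        skip = set(continuous) | {
            "patient_id", "group", "excluded_reason", "sex",
            "duration_days", "total_ome_mg",
        }
        categorical = tuple(
            c for c in kept.columns
            if c not in skip and set(kept[c].dropna().unique()) <= {0, 1}
        )

    by_group = {g: kept[kept["group"] == g] for g in groups_present}
    # groups with fewer than 2 observations get not-computable p-values
    case_groups = [g for g in groups_present if g != 0 and len(by_group[g]) >= 2]
    can_test = 0 in by_group and len(by_group.get(0, ())) >= 2 and case_groups

    out = []
    for var in continuous:
        rec = {"variable": var, "type": "continuous"}
        for g in (0, 1, 2):
            sub = by_group.get(g)
            rec[f"mean_{GROUP_NAMES[g]}"] = float(sub[var].mean()) if sub is not None else np.nan
            rec[f"sd_{GROUP_NAMES[g]}"] = float(sub[var].std(ddof=1)) if sub is not None else np.nan
        if can_test:
            res = dunnett_test(
                by_group[0][var].to_numpy(float),
                {GROUP_NAMES[g]: by_group[g][var].to_numpy(float) for g in case_groups},
            )
            for name, c in res.by_group.items():
                rec[f"p_{name}"] = c.p_adjusted
        out.append(rec)

    for var in categorical:
        rec = {"variable": var, "type": "categorical"}
        for g in (0, 1, 2):
            sub = by_group.get(g)
            if sub is None:
                rec[f"n_{GROUP_NAMES[g]}"] = np.nan
                rec[f"pct_{GROUP_NAMES[g]}"] = np.nan
            else:
                n_pos = int(sub[var].sum())
                rec[f"n_{GROUP_NAMES[g]}"] = n_pos
                rec[f"pct_{GROUP_NAMES[g]}"] = format_pct(n_pos, len(sub))
        if can_test:
            res = steel_test(
                by_group[0][var].to_numpy(float),
                {GROUP_NAMES[g]: by_group[g][var].to_numpy(float) for g in case_groups},
            )
            for name, c in res.by_group.items():
                rec[f"p_{name}"] = c.p_adjusted
        out.append(rec)

    return pd.DataFrame(out)
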