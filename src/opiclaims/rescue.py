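"""Rescue-medication status and intensity during the prescription episode.

Rescue opioids are immediate-release formulations dispensed for
breakthrough pain; base opioids provide around-the-clock control.  Each
patient's episode is labelled ``rescue_only`` / ``base_only`` /
``base_and_rescue`` from the roles present, and for rescue recipients
two intensity measures are computed over the episode duration:

* mean daily number of rescue uses — dispensed rescue dose-units
  (``n_units``) divided by the episode duration in days.  Claims data
  observe dispensing, not ingestion, so this is a dispensing-based
  approximation; units of non-convertible drugs still count here.
* mean daily rescue OME — rescue milligrams (oral-morphine equivalent)
  divided by the episode duration; fentanyl sublingual/buccal tablets
  are excluded from this dose sum (no guideline conversion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .claims import ClaimsBundle, DrugDictionary, NOT_CONVERTIBLE
from .cohort import GROUP_NAMES, format_pct
from .episodes import Episode
from .manyone import dunnett_test, steel_test

__all__ = [
    "prescription_status",
    "rescue_intensity",
    "rescue_rows",
    "rescue_summary",
]

STATUSES = ("rescue_only", "base_only", "base_and_rescue")


def _episode_rx(prescriptions: pd.DataFrame, episode: Episode) -> pd.DataFrame:
    return prescriptions[
        (prescriptions["start_date"] >= episode.index_date)
        & (prescriptions["start_date"] <= episode.end_date)
    ]


def prescription_status(
    prescriptions: pd.DataFrame, dictionary: DrugDictionary, episode: Episode
) -> str:
    """Status from the opioid roles present within the episode."""
    rx = _episode_rx(prescriptions, episode)
    roles = set(rx["drug_code"].map(lambda c: dictionary.role_of(c)))
    has_rescue = "rescue_opioid" in roles
    has_base = "base_opioid" in roles
    if has_rescue and has_base:
        return "base_and_rescue"
    if has_rescue:
        return "rescue_only"
    if has_base:
        return "base_only"
    raise ValueError("episode contains no opioid prescriptions")


def rescue_intensity(
    prescriptions: pd.DataFrame,
    dictionary: DrugDictionary,
    ome_table: Mapping[str, float | None],
    episode: Episode,
) -> tuple[float, float]:
    """(mean daily rescue uses, mean daily rescue OME mg) for one patient.

    Fatal when the patient has no rescue prescription in the episode.
    """
    rx = _episode_rx(prescriptions, episode)
    rescue = rx[rx["drug_code"].map(lambda c: dictionary.role_of(c) == "rescue_opioid")]
    if rescue.empty:
        raise ValueError("rescue_intensity called on a patient without rescue prescriptions")
    uses = float(rescue["n_units"].sum())
    total_mg = 0.0
    for _, row in rescue.iterrows():
        factor = ome_table.get(row["drug_code"], NOT_CONVERTIBLE)
        if factor is NOT_CONVERTIBLE:
            continue  # units counted above, dose excluded
        total_mg += float(row["daily_dose_mg"]) * factor * int(row["days_supplied"])
    d = episode.duration_days
    return uses / d, total_mg / d


def rescue_rows(
    bundle: ClaimsBundle,
    episodes: dict[str, Episode],
    groups: dict[str, int],
) -> pd.DataFrame:
    """Per-patient rescue status and intensity for all grouped patients."""
    table = bundle.dictionary.ome_table()
    rx_groups = (
        dict(iter(bundle.prescriptions.groupby("patient_id")))
        if len(bundle.prescriptions)
        else {}
    )
    out = []
    for pid, g in groups.items():
        ep = episodes[pid]
        rx = rx_groups.get(pid, bundle.prescriptions.iloc[0:0])
        status = prescription_status(rx, bundle.dictionary, ep)
        rec = {"patient_id": pid, "group": g, "status": status,
               "daily_uses": np.nan, "daily_rescue_ome": np.nan}
        if status != "base_only":
            rec["daily_uses"], rec["daily_rescue_ome"] = rescue_intensity(
                rx, bundle.dictionary, table, ep
            )
        out.append(rec)
    return pd.DataFrame(out)


def rescue_summary(rows: pd.DataFrame) -> pd.DataFrame:
    """Table-3-shaped summary with many-to-one p-values.

    Status counts/percentages per group with a Steel test on the
    any-rescue indicator; among rescue recipients, mean (SD) of the two
    intensity measures with Dunnett tests.
    """
    groups_present = sorted(rows["group"].unique())
    by_group = {g: rows[rows["group"] == g] for g in groups_present}
    case_groups = [g for g in groups_present if g != 0 and len(by_group[g]) >= 2]
    can_test = 0 in by_group and len(by_group.get(0, ())) >= 2 and bool(case_groups)

    out = []
    steel_p: dict[str, float] = {}
    if can_test:
        res = steel_test(
            (by_group[0]["status"] != "base_only").to_numpy(float),
            {
                GROUP_NAMES[g]: (by_group[g]["status"] != "base_only").to_numpy(float)
                for g in case_groups
            },
        )
        steel_p = res.p_values()
    for status in STATUSES:
        rec = {"variable": status, "type": "status"}
        for g in (0, 1, 2):
            sub = by_group.get(g)
            if sub is None:
                rec[f"n_{GROUP_NAMES[g]}"] = np.nan
                rec[f"pct_{GROUP_NAMES[g]}"] = np.nan
            else:
                n = int((sub["status"] == status).sum())
                rec[f"n_{GROUP_NAMES[g]}"] = n
                rec[f"pct_{GROUP_NAMES[g]}"] = format_pct(n, len(sub))
        if status == "rescue_only":
            rec.update({f"p_{k}": v for k, v in steel_p.items()})
        out.append(rec)

    for var in ("daily_uses", "daily_rescue_ome"):
        rec = {"variable": var, "type": "continuous"}
        recips = {g: by_group[g][var].dropna() for g in groups_present}
        for g in (0, 1, 2):
            vals = recips.get(g)
            rec[f"mean_{GROUP_NAMES[g]}"] = float(vals.mean()) if vals is not None and len(vals) else np.nan
            rec[f"sd_{GROUP_NAMES[g]}"] = (
                float(vals.std(ddof=1)) if vals is not None and len(vals) > 1 else np.nan
            )
        if can_test and all(len(recips.get(g, [])) >= 2 for g in [0] + case_groups):
            res = dunnett_test(
                recips[0].to_numpy(float),
                {GROUP_NAMES[g]: recips[g].to_numpy(float) for g in case_groups},
            )
            rec.update({f"p_{k}": v for k, v in res.p_values().items()})
        out.append(rec)
    return pd.DataFrame(out)
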