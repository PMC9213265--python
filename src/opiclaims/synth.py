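"""Synthetic claims-bundle generator with planted ground truth.

Every pipeline stage — eligibility, episode construction, OME dosing,
cohort classification, covariate extraction, rescue metrics and the
ordinal regression — can be exercised end-to-end on bundles produced
here, with the generating labels and parameters known exactly.

Generation order (per patient, one RNG stream per patient derived from
``(seed, patient index)`` so output is stable under ``n_patients``
changes):

1. binary risk-factor flags are drawn from ``covariate_prevalences``
   (bone metastasis implies the distant-metastasis flag, as in ICD-10
   coding where C79.5 sits inside C77–C79);
2. the ordinal group (control / case I / case II) is drawn from the
   proportional-odds model P(Y >= k | x) = logistic(alpha_k + x'beta)
   using ``true_betas`` and the strictly decreasing ``true_intercepts``;
3. an episode consistent with the group's duration/dose band is
   materialized on the calendar: opioid prescriptions tile the true
   span with within-episode uncovered gaps drawn on [0, gap_max]
   (always < 30 days), the last prescription ending exactly on the true
   end date; optional post-episode prescriptions start at least 31 days
   after the end (>= 30 uncovered days);
4. risk-factor records (diagnoses, drug-class prescriptions,
   treatment-context codes) are planted in the window their flag refers
   to (pre-index vs during-episode vs any time).

Two excluded strata emulate real attrition: a ``long_low_frac`` share of
patients get long episodes below the high-dose cut, and a
``nonconvertible_frac`` share get episodes containing only
non-convertible opioids (dose not calculable).  Their true labels carry
the exclusion reason instead of a group.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .claims import ClaimsBundle, CodeMap, DrugDictionary, default_code_map, default_drug_dictionary

__all__ = ["SimulationConfig", "GroundTruth", "generate_bundle", "generate_regression_dataset"]


def _default_prevalences() -> dict[str, float]:
    return {
        "back_pain": 0.45,
        "bone_metastasis": 0.16,
        "distant_metastasis": 0.25,
        "schizophrenia": 0.11,
        "mood_disorders": 0.12,
        "anxiety": 0.17,
        "spondylosis": 0.08,
        "spinal_stenosis": 0.05,
        "osteoarthritis_knee": 0.03,
        "diabetes": 0.29,
        "pre_non_opioid_analgesic": 0.75,
        "dur_non_opioid_analgesic": 0.80,
        "pre_gabapentinoid": 0.08,
        "dur_gabapentinoid": 0.12,
        "dur_TCA": 0.012,
        "dur_SSRI": 0.012,
        "dur_SNRI": 0.03,
        "dur_antiepileptic": 0.04,
        "pre_radiotherapy": 0.30,
        "dur_radiotherapy": 0.37,
        "pre_chemotherapy": 0.50,
        "dur_chemotherapy": 0.70,
    }


def _default_betas() -> dict[str, float]:
    # log-odds echoing the magnitude ordering of the fitted analysis
    return {
        "back_pain": 0.297,
        "distant_metastasis": 0.589,
        "dur_gabapentinoid": 0.80,
        "dur_SNRI": 0.889,
        "dur_non_opioid_analgesic": 0.90,
        "dur_chemotherapy": 0.718,
    }


def _default_status_probs() -> dict[int, tuple[float, float]]:
    # group -> (P(rescue_only), P(base_only)); remainder is base_and_rescue
    return {0: (0.235, 0.259), 1: (0.0, 0.045), 2: (0.006, 0.026)}


@dataclass
class SimulationConfig:
    n_patients: int = 1000
    seed: int = 0
    calendar_start: _dt.date = _dt.date(2008, 4, 1)
    calendar_end: _dt.date = _dt.date(2020, 7, 31)
    covariate_prevalences: dict[str, float] = field(default_factory=_default_prevalences)
    true_betas: dict[str, float] = field(default_factory=_default_betas)
    true_intercepts: tuple[float, float] = (-4.6, -4.8)
    # episode duration (days): lognormal mixture by group band
    short_mu: float = 3.4
    short_sigma: float = 0.9
    long_mu: float = 6.2
    long_sigma: float = 0.6
    duration_cap: int = 2500
    # mean daily OME (mg/day): lognormal by group band
    control_dose_mu: float = 3.2
    control_dose_sigma: float = 1.0
    case_dose_mu: float = 5.2
    case_dose_sigma: float = 0.4
    dose_cap: float = 2000.0
    # within-episode uncovered gaps
    gap_prob: float = 0.3
    gap_max: int = 29
    rx_len_min: int = 7
    rx_len_max: int = 30
    # rescue dispensing
    rescue_rate: float = 1.0  # mean dispensed units per day among recipients
    status_probs: dict[int, tuple[float, float]] = field(default_factory=_default_status_probs)
    # excluded strata and extras
    long_low_frac: float = 0.25
    nonconvertible_frac: float = 0.004
    post_episode_rx_prob: float = 0.10
    delay_max: int = 365  # max days from cancer diagnosis to index
    thresholds_long: int = 183
    thresholds_very_long: int = 730
    high_dose_mg: float = 120.0

    def validate(self) -> "SimulationConfig":
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for name, p in self.covariate_prevalences.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence of {name!r} outside [0, 1]")
        a1, a2 = self.true_intercepts
        if not a1 > a2:
            raise ValueError(
                "true_intercepts must be strictly decreasing "
                "(P(Y>=1) >= P(Y>=2) requires alpha_1 > alpha_2)"
            )
        if not 0 <= self.gap_max <= 29:
            raise ValueError("gap_max must lie in [0, 29]")
        window = (self.calendar_end - self.calendar_start).days
        if window < self.thresholds_very_long + 32:
            raise ValueError(
                "infeasible config: calendar window shorter than the longest episode band"
            )
        missing = set(self.true_betas) - set(self.covariate_prevalences)
        if missing:
            raise ValueError(f"true_betas refer to unknown covariates: {sorted(missing)}")
        return self


@dataclass
class GroundTruth:
    """Per-patient generating labels plus the generating parameters."""

    frame: pd.DataFrame  # patient_id, true_group, excluded_reason, episode span, flags
    config: SimulationConfig

    @property
    def labelled(self) -> pd.DataFrame:
        return self.frame[self.frame["true_group"].notna()]


# -- planting resolver -------------------------------------------------------


def _plant_spec(
    name: str, code_map: CodeMap, dictionary: DrugDictionary
) -> tuple[str, str, str]:
    """Resolve a covariate name to (record kind, code, window)."""
    if name.startswith(("pre_", "dur_")):
        window, base = name[:3], name[4:]
        if base in code_map.treatments:
            return ("dx", code_map.treatments[base][0], window)
        codes = dictionary.codes_with_role(base)
        if codes:
            return ("rx", codes[0], window)
        raise ValueError(f"cannot plant covariate {name!r}: unknown class {base!r}")
    for section in (code_map.comorbidities, code_map.metastasis, code_map.cancer_sites):
        if name in section:
            return ("dx", section[name][0], "any")
    raise ValueError(f"cannot plant covariate {name!r}")


_PRIMARY_SITES = ("C18", "C34", "C50", "C61", "C16")  # colon, lung, breast, prostate, stomach


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, lo: float, hi: float
) -> float:
    for _ in range(200):
        v = rng.lognormal(mu, sigma)
        if lo <= v <= hi:
            return v
    return float(np.clip(rng.lognormal(mu, sigma), lo, hi))


def _tile_episode(
    rng: np.random.Generator, duration: int, cfg: SimulationConfig
) -> list[tuple[int, int]]:
    """Prescription blocks (offset, length) covering [0, duration-1].

    The first block starts at offset 0 and the last ends exactly at
    duration - 1; uncovered gaps between blocks are < 30 days.
    """
    blocks: list[tuple[int, int]] = []
    pos = 0
    while pos < duration:
        length = int(min(rng.integers(cfg.rx_len_min, cfg.rx_len_max + 1), duration - pos))
        blocks.append((pos, length))
        pos += length
        if pos >= duration:
            break
        if cfg.gap_max > 0 and rng.random() < cfg.gap_prob:
            gap = int(rng.integers(1, cfg.gap_max + 1))
            pos += int(min(gap, max(0, duration - pos - 1)))
    return blocks


def generate_bundle(config: SimulationConfig) -> tuple[ClaimsBundle, GroundTruth]:
    """Generate a validated claims bundle and its ground truth."""
    cfg = config.validate()
    code_map = default_code_map()
    dictionary = default_drug_dictionary()
    ome = dictionary.ome_table()

    cov_names = list(cfg.covariate_prevalences)
    specs = {name: _plant_spec(name, code_map, dictionary) for name in cov_names}
    a1, a2 = cfg.true_intercepts
    window = (cfg.calendar_end - cfg.calendar_start).days

    patients, diagnoses, prescriptions, truth_rows = [], [], [], []
    for i in range(cfg.n_patients):
        rng = np.random.default_rng([cfg.seed, i])
        pid = f"P{i:06d}"

        flags = {n: int(rng.random() < cfg.covariate_prevalences[n]) for n in cov_names}
        if flags.get("bone_metastasis") and "distant_metastasis" in flags:
            flags["distant_metastasis"] = 1  # C79.5 lies inside C77-C79

        eta = sum(cfg.true_betas[n] * flags[n] for n in cfg.true_betas)
        u = rng.random()
        group = int(u < expit(a1 + eta)) + int(u < expit(a2 + eta))

        stratum = rng.random()
        excluded_reason = None
        if stratum < cfg.long_low_frac:
            excluded_reason = "long_low_dose"
        elif stratum < cfg.long_low_frac + cfg.nonconvertible_frac:
            excluded_reason = "dose_not_calculable"

        # duration / dose consistent with group (or exclusion stratum)
        cap = min(cfg.duration_cap, window - cfg.delay_max - 92)
        if excluded_reason == "long_low_dose":
            duration = int(
                round(_truncated_lognormal(rng, cfg.long_mu, cfg.long_sigma,
                                           cfg.thresholds_long, cap))
            )
            dose = _truncated_lognormal(rng, cfg.control_dose_mu, cfg.control_dose_sigma,
                                        0.5, cfg.high_dose_mg * 0.95)
        elif excluded_reason == "dose_not_calculable":
            duration = int(round(_truncated_lognormal(rng, cfg.short_mu, cfg.short_sigma,
                                                      1, cfg.thresholds_long - 1)))
            dose = _truncated_lognormal(rng, cfg.control_dose_mu, cfg.control_dose_sigma,
                                        0.5, cfg.dose_cap)
        elif group == 0:
            duration = int(round(_truncated_lognormal(rng, cfg.short_mu, cfg.short_sigma,
                                                      1, cfg.thresholds_long - 1)))
            dose = _truncated_lognormal(rng, cfg.control_dose_mu, cfg.control_dose_sigma,
                                        0.5, cfg.dose_cap)
        else:
            lo, hi = (
                (cfg.thresholds_long, cfg.thresholds_very_long - 1)
                if group == 1
                else (cfg.thresholds_very_long, cap)
            )
            duration = int(round(_truncated_lognormal(rng, cfg.long_mu, cfg.long_sigma, lo, hi)))
            duration = int(np.clip(duration, lo, hi))
            dose = _truncated_lognormal(rng, cfg.case_dose_mu, cfg.case_dose_sigma,
                                        cfg.high_dose_mg, cfg.dose_cap)

        # calendar placement: dx -> index -> episode -> end_of_data
        delay = int(rng.integers(1, cfg.delay_max + 1))
        needed = max(duration + 31, cfg.thresholds_very_long) + 61
        latest_dx = window - needed - delay
        dx_off = int(rng.integers(0, max(latest_dx, 0) + 1))
        dx_date = cfg.calendar_start + _dt.timedelta(days=dx_off)
        index_date = dx_date + _dt.timedelta(days=delay)
        end_date = index_date + _dt.timedelta(days=duration - 1)
        eod = index_date + _dt.timedelta(
            days=max(duration + 30, cfg.thresholds_very_long) + int(rng.integers(0, 61))
        )
        eod = min(eod, cfg.calendar_end)

        age = int(np.clip(rng.normal(64, 12), 20, 95))
        patients.append(
            {
                "patient_id": pid,
                "sex": "male" if rng.random() < 0.6 else "female",
                "birth_year": index_date.year - age,
                "end_of_data": eod,
            }
        )
        site = _PRIMARY_SITES[int(rng.integers(len(_PRIMARY_SITES)))]
        diagnoses.append({"patient_id": pid, "icd10_code": site, "date": dx_date})

        # opioid tiling of the true span
        status_ro, status_bo = cfg.status_probs.get(group, (0.0, 0.0))
        if excluded_reason == "dose_not_calculable":
            tiling_drug, status = "FEN_BUC", "rescue_only"
        else:
            s = rng.random()
            if s < status_ro:
                tiling_drug, status = "MOR_IR", "rescue_only"
            elif s < status_ro + status_bo:
                tiling_drug, status = "MOR_OR", "base_only"
            else:
                tiling_drug, status = "MOR_OR", "base_and_rescue"

        blocks = _tile_episode(rng, duration, cfg)
        covered = sum(length for _, length in blocks)
        daily_mg = dose * duration / covered  # keeps mean over duration at `dose`
        rescue_mg_total = 0.0
        if status == "base_and_rescue":
            n_disp = max(1, int(round(duration * cfg.rescue_rate / 3.0)))
            n_disp = min(n_disp, 400)
            covered_days = np.concatenate(
                [np.arange(off, off + length) for off, length in blocks]
            )
            days = rng.choice(covered_days, size=n_disp)
            for day in days:
                units = 1 + int(rng.poisson(2.0))
                rx_dose = 10.0
                prescriptions.append(
                    {
                        "patient_id": pid,
                        "drug_code": "MOR_IR",
                        "start_date": index_date + _dt.timedelta(days=int(day)),
                        "days_supplied": 1,
                        "daily_dose_mg": rx_dose,
                        "n_units": units,
                    }
                )
                rescue_mg_total += rx_dose
        for off, length in blocks:
            prescriptions.append(
                {
                    "patient_id": pid,
                    "drug_code": tiling_drug,
                    "start_date": index_date + _dt.timedelta(days=off),
                    "days_supplied": length,
                    "daily_dose_mg": round(daily_mg, 6),
                    "n_units": length,
                }
            )
        if rng.random() < cfg.post_episode_rx_prob:
            post_start = end_date + _dt.timedelta(days=31 + int(rng.integers(0, 30)))
            if post_start + _dt.timedelta(days=13) <= eod:
                prescriptions.append(
                    {
                        "patient_id": pid,
                        "drug_code": "MOR_OR",
                        "start_date": post_start,
                        "days_supplied": 14,
                        "daily_dose_mg": 30.0,
                        "n_units": 14,
                    }
                )

        # plant risk-factor records in their windows
        for name in cov_names:
            if not flags[name]:
                continue
            kind, code, win = specs[name]
            if win == "pre":
                lo_d, hi_d = dx_date, index_date - _dt.timedelta(days=1)
            elif win == "dur":
                lo_d, hi_d = index_date, end_date
            else:
                lo_d, hi_d = dx_date, end_date
            span = (hi_d - lo_d).days
            when = lo_d + _dt.timedelta(days=int(rng.integers(0, span + 1)))
            if kind == "dx":
                diagnoses.append({"patient_id": pid, "icd10_code": code, "date": when})
            else:
                prescriptions.append(
                    {
                        "patient_id": pid,
                        "drug_code": code,
                        "start_date": when,
                        "days_supplied": 14,
                        "daily_dose_mg": 100.0,
                        "n_units": 14,
                    }
                )

        true_mean = dose + (
            rescue_mg_total / duration if excluded_reason != "dose_not_calculable" else 0.0
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "true_group": group if excluded_reason is None else np.nan,
                "excluded_reason": excluded_reason,
                "index_date": index_date,
                "end_date": end_date,
                "duration_days": duration,
                "mean_daily_ome": true_mean if excluded_reason != "dose_not_calculable" else np.nan,
                **flags,
            }
        )

    bundle = ClaimsBundle(
        pd.DataFrame(patients, columns=["patient_id", "sex", "birth_year", "end_of_data"]),
        pd.DataFrame(diagnoses, columns=["patient_id", "icd10_code", "date"]),
        pd.DataFrame(
            prescriptions,
            columns=["patient_id", "drug_code", "start_date", "days_supplied",
                     "daily_dose_mg", "n_units"],
        ),
        dictionary,
        code_map,
    )
    if cfg.n_patients:
        bundle.validate()
    truth = GroundTruth(pd.DataFrame(truth_rows), cfg)
    return bundle, truth


def generate_regression_dataset(
    n: int,
    true_betas: dict[str, float],
    true_intercepts: tuple[float, float],
    seed: int,
    prevalences: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Covariates and an ordinal outcome drawn from the cumulative-logit model.

    Binary covariates with the given prevalences (0.5 by default) and
    Y in {0, 1, 2} with P(Y >= k | x) = logistic(alpha_k + x'beta).
    Used for parameter-recovery tests of the proportional-odds fitter.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    a1, a2 = true_intercepts
    if not a1 > a2:
        raise ValueError("intercepts must be strictly decreasing (alpha_1 > alpha_2)")
    rng = np.random.default_rng(seed)
    names = list(true_betas)
    prev = prevalences or {}
    x = np.column_stack(
        [(rng.random(n) < prev.get(name, 0.5)).astype(float) for name in names]
    ) if names else np.empty((n, 0))
    eta = x @ np.array([true_betas[name] for name in names]) if names else np.zeros(n)
    u = rng.random(n)
    y = (u < expit(a1 + eta)).astype(int) + (u < expit(a2 + eta)).astype(int)
    params = {"betas": dict(true_betas), "intercepts": tuple(true_intercepts)}
    return pd.DataFrame(x, columns=names), pd.Series(y, name="group"), params
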