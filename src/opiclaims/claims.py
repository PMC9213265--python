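"""Domain types and CSV I/O for claims-style data.

A claims bundle holds three raw tables — patients, diagnoses,
prescriptions — plus a drug dictionary mapping drug codes to analgesic
roles and oral-morphine-equivalent (OME) conversion factors, and a
code map translating ICD-10 prefixes into analysis covariates.

Conventions
-----------
* Dates are ISO-8601 strings on disk and ``datetime.date`` in memory;
  all day intervals are closed and 1-based (a prescription starting on
  day *s* with ``days_supplied`` = *d* covers days *s* .. *s* + *d* − 1
  inclusive).
* ``daily_dose_mg`` is the drug's own active-ingredient milligrams per
  day, before any morphine-equivalent conversion.
* An OME factor of :data:`NOT_CONVERTIBLE` marks formulations (fentanyl
  sublingual/buccal tablets, methadone) that have no guideline
  conversion to oral morphine; they are excluded from dose sums but not
  from coverage or dispensing counts.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "NOT_CONVERTIBLE",
    "DRUG_ROLES",
    "OPIOID_ROLES",
    "PatientRecord",
    "DiagnosisRecord",
    "PrescriptionRecord",
    "DrugInfo",
    "DrugDictionary",
    "CodeMap",
    "ClaimsBundle",
    "BundleError",
    "default_drug_dictionary",
    "default_code_map",
    "read_bundle",
    "write_bundle",
]

#: Sentinel for drugs with no defined oral-morphine conversion.
NOT_CONVERTIBLE = None

#: Reserved token used for NOT_CONVERTIBLE in drugs.csv (blank also accepted).
_NC_TOKEN = "NC"

DRUG_ROLES = (
    "base_opioid",
    "rescue_opioid",
    "non_opioid_analgesic",
    "TCA",
    "SSRI",
    "SNRI",
    "gabapentinoid",
    "antiepileptic",
    "antiarrhythmic",
    "NMDA_antagonist",
    "central_muscle_relaxant",
    "other",
)

#: Roles that count as opioids for eligibility and episode coverage.
OPIOID_ROLES = ("base_opioid", "rescue_opioid")

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}([.][0-9]+)?$")


class BundleError(ValueError):
    """Raised for malformed or internally inconsistent claims data."""


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str  # "male" | "female"
    birth_year: int
    end_of_data: _dt.date  # death or last record

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise BundleError(f"invalid sex {self.sex!r} for patient {self.patient_id}")


@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    icd10_code: str
    date: _dt.date

    def __post_init__(self) -> None:
        if not _ICD10_RE.match(self.icd10_code):
            raise BundleError(f"malformed ICD-10 code {self.icd10_code!r}")


@dataclass(frozen=True)
class PrescriptionRecord:
    patient_id: str
    drug_code: str
    start_date: _dt.date
    days_supplied: int
    daily_dose_mg: float
    n_units: int = 1  # dispensed dose-units, used for rescue counting

    def __post_init__(self) -> None:
        if self.days_supplied < 1:
            raise BundleError(
                f"days_supplied must be >= 1 (patient {self.patient_id}, drug {self.drug_code})"
            )
        if self.daily_dose_mg < 0:
            raise BundleError(
                f"negative daily_dose_mg (patient {self.patient_id}, drug {self.drug_code})"
            )
        if self.n_units < 1:
            raise BundleError(
                f"n_units must be >= 1 (patient {self.patient_id}, drug {self.drug_code})"
            )

    @property
    def end_date(self) -> _dt.date:
        """Last calendar day covered (closed interval)."""
        return self.start_date + _dt.timedelta(days=self.days_supplied - 1)


@dataclass(frozen=True)
class DrugInfo:
    name: str
    role: str
    ome_factor: float | None  # mg oral morphine per mg drug, or NOT_CONVERTIBLE

    def __post_init__(self) -> None:
        if self.role not in DRUG_ROLES:
            raise BundleError(f"unknown drug role {self.role!r} for {self.name!r}")
        if self.ome_factor is not NOT_CONVERTIBLE and self.ome_factor < 0:
            raise BundleError(f"negative OME factor for {self.name!r}")


class DrugDictionary(Mapping[str, DrugInfo]):
    """Immutable drug_code → :class:`DrugInfo` lookup."""

    def __init__(self, entries: Mapping[str, DrugInfo]):
        self._entries = dict(entries)

    def __getitem__(self, code: str) -> DrugInfo:
        return self._entries[code]

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, DrugDictionary) and self._entries == other._entries

    def role_of(self, code: str) -> str:
        return self._entries[code].role

    def is_opioid(self, code: str) -> bool:
        return self._entries[code].role in OPIOID_ROLES

    def ome_table(self) -> dict[str, float | None]:
        """Map drug_code → OME factor (or NOT_CONVERTIBLE), opioids only."""
        return {
            c: info.ome_factor
            for c, info in self._entries.items()
            if info.role in OPIOID_ROLES
        }

    def codes_with_role(self, role: str) -> tuple[str, ...]:
        return tuple(c for c, info in self._entries.items() if info.role == role)


# ---------------------------------------------------------------------------
# Code map: ICD-10 prefixes -> covariates
# ---------------------------------------------------------------------------


def _expand_prefix(spec: str) -> tuple[str, ...]:
    """Expand "C18-C21" into ("C18", "C19", "C20", "C21"); pass plain prefixes through."""
    if "-" not in spec:
        return (spec,)
    lo, hi = spec.split("-")
    if lo[0] != hi[0] or len(lo) != 3 or len(hi) != 3:
        raise BundleError(f"bad ICD-10 range {spec!r}")
    letter = lo[0]
    return tuple(f"{letter}{i:02d}" for i in range(int(lo[1:]), int(hi[1:]) + 1))


def _expand_all(specs: Iterable[str]) -> tuple[str, ...]:
    out: list[str] = []
    for s in specs:
        out.extend(_expand_prefix(s))
    return tuple(out)


@dataclass(frozen=True)
class CodeMap:
    """Configurable mapping from ICD-10 code prefixes to covariate names.

    ``cancer_sites``, ``comorbidities`` and ``metastasis`` map a covariate
    name to a tuple of code prefixes (matched by ``str.startswith``).
    ``treatments`` maps treatment names (operative, radiotherapy,
    chemotherapy, nerve_block) to the procedure-context codes that encode
    them in the diagnosis table.  ``cancer_prefixes`` defines which codes
    count as a cancer diagnosis for eligibility.
    """

    cancer_sites: Mapping[str, tuple[str, ...]]
    comorbidities: Mapping[str, tuple[str, ...]]
    metastasis: Mapping[str, tuple[str, ...]]
    treatments: Mapping[str, tuple[str, ...]]
    cancer_prefixes: tuple[str, ...] = ("C",)

    def matches(self, code: str, prefixes: Iterable[str]) -> bool:
        return any(code.startswith(p) for p in prefixes)

    def is_cancer(self, code: str) -> bool:
        # treatment-context codes are never cancer diagnoses even if C-coded
        return self.matches(code, self.cancer_prefixes)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CodeMap":
        def conv(section) -> dict[str, tuple[str, ...]]:
            return {k: _expand_all(v) for k, v in section.items()}

        return cls(
            cancer_sites=conv(d.get("cancer_sites", {})),
            comorbidities=conv(d.get("comorbidities", {})),
            metastasis=conv(d.get("metastasis", {})),
            treatments={k: tuple(v) for k, v in d.get("treatments", {}).items()},
            cancer_prefixes=_expand_all(d.get("cancer_prefixes", ["C"])),
        )

    def to_dict(self) -> dict:
        return {
            "cancer_sites": {k: list(v) for k, v in self.cancer_sites.items()},
            "comorbidities": {k: list(v) for k, v in self.comorbidities.items()},
            "metastasis": {k: list(v) for k, v in self.metastasis.items()},
            "treatments": {k: list(v) for k, v in self.treatments.items()},
            "cancer_prefixes": list(self.cancer_prefixes),
        }


def default_code_map() -> CodeMap:
    """Default ICD-10 covariate map (overridable via JSON config).

    Cancer-site groups follow the conventional ICD-10 C-block layout;
    comorbidity prefixes are declared defaults for common pain-relevant
    conditions.  Treatment-context codes piggyback on Z-codes
    (aftercare / therapy-session codes) plus Z51.8 for nerve block.
    """
    return CodeMap.from_dict(
        {
            "cancer_prefixes": ["C"],
            "cancer_sites": {
                "lip_oral_pharynx": ["C00-C14"],
                "esophagus": ["C15"],
                "stomach": ["C16"],
                "small_intestine": ["C17"],
                "large_intestine_anus": ["C18-C21"],
                "liver_bile_ducts": ["C22"],
                "gallbladder_biliary": ["C23-C24"],
                "pancreas": ["C25"],
                "other_digestive": ["C26"],
                "respiratory_intrathoracic": ["C30-C39"],
                "bone_articular_cartilage": ["C40-C41"],
                "melanoma_skin": ["C43-C44"],
                "mesothelial_soft_tissue": ["C45-C49"],
                "breast": ["C50"],
                "female_genital": ["C51-C58"],
                "male_genital": ["C60-C63"],
                "urinary_tract": ["C64-C68"],
                "eye_brain_cns": ["C69-C72"],
                "thyroid_endocrine": ["C73-C75"],
                "ill_defined_secondary": ["C76", "C80"],
                "lymphoid_hematopoietic": ["C81-C96"],
                "multiple_sites": ["C97"],
            },
            "metastasis": {
                "bone_metastasis": ["C79.5"],
                "distant_metastasis": ["C77-C79"],
            },
            "comorbidities": {
                "herpes_zoster": ["B02"],
                "osteoarthritis_knee": ["M17"],
                "back_pain": ["M54"],
                "spinal_stenosis": ["M48.0"],
                "spondylosis": ["M47"],
                "other_bone_disorders": ["M89"],
                "alcohol_dependence": ["F10"],
                "psychoactive_substance_dependence": ["F11-F19"],
                "schizophrenia": ["F20-F29"],
                "mood_disorders": ["F30-F39"],
                "anxiety": ["F40-F48"],
                "sleep_disorders": ["G47"],
                "delirium": ["F05"],
                "dementia": ["F00-F03"],
                "diabetes": ["E10-E14"],
                "hepatic_disorder": ["K70-K77"],
                "chronic_kidney_disease": ["N18"],
            },
            "treatments": {
                "operative": ["Z98"],
                "radiotherapy": ["Z51.0"],
                "chemotherapy": ["Z51.1"],
                "nerve_block": ["Z51.8"],
            },
        }
    )


def default_drug_dictionary() -> DrugDictionary:
    """Default drug dictionary with guideline OME factors.

    Factors are mg oral morphine per mg of drug; oral morphine is the
    1.0 reference (30 mg oral morphine basis).  Fentanyl sublingual and
    buccal tablets and methadone carry NOT_CONVERTIBLE.
    """
    e = {
        "MOR_OR": DrugInfo("morphine oral", "base_opioid", 1.0),
        "MOR_SUPP": DrugInfo("morphine suppository", "base_opioid", 1.5),
        "OXY_OR": DrugInfo("oxycodone oral", "base_opioid", 1.5),
        "FEN_TTS": DrugInfo("fentanyl transdermal patch", "base_opioid", 100.0),
        "TAP_OR": DrugInfo("tapentadol oral", "base_opioid", 0.3),
        "HYM_OR": DrugInfo("hydromorphone oral", "base_opioid", 5.0),
        "MET_OR": DrugInfo("methadone oral", "base_opioid", NOT_CONVERTIBLE),
        # rescue (immediate-release) formulations
        "OXY_IR": DrugInfo("oxycodone powder IR", "rescue_opioid", 1.5),
        "MOR_IR": DrugInfo("morphine hydrochloride IR tablet", "rescue_opioid", 1.0),
        "MOR_SOL": DrugInfo("morphine oral solution", "rescue_opioid", 1.0),
        "HYM_IR": DrugInfo("hydromorphone IR tablet", "rescue_opioid", 5.0),
        "FEN_SL": DrugInfo("fentanyl sublingual tablet", "rescue_opioid", NOT_CONVERTIBLE),
        "FEN_BUC": DrugInfo("fentanyl buccal tablet", "rescue_opioid", NOT_CONVERTIBLE),
        # non-opioid pain-related classes
        "NSAID": DrugInfo("NSAID", "non_opioid_analgesic", NOT_CONVERTIBLE),
        "ACET": DrugInfo("acetaminophen", "non_opioid_analgesic", NOT_CONVERTIBLE),
        "TCA1": DrugInfo("amitriptyline", "TCA", NOT_CONVERTIBLE),
        "SSRI1": DrugInfo("sertraline", "SSRI", NOT_CONVERTIBLE),
        "SNRI1": DrugInfo("duloxetine", "SNRI", NOT_CONVERTIBLE),
        "GABA1": DrugInfo("pregabalin", "gabapentinoid", NOT_CONVERTIBLE),
        "AED1": DrugInfo("carbamazepine", "antiepileptic", NOT_CONVERTIBLE),
        "AAR1": DrugInfo("mexiletine", "antiarrhythmic", NOT_CONVERTIBLE),
        "NMDA1": DrugInfo("ketamine oral", "NMDA_antagonist", NOT_CONVERTIBLE),
        "CMR1": DrugInfo("eperisone", "central_muscle_relaxant", NOT_CONVERTIBLE),
    }
    return DrugDictionary(e)


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

_PATIENT_COLS = ["patient_id", "sex", "birth_year", "end_of_data"]
_DX_COLS = ["patient_id", "icd10_code", "date"]
_RX_COLS = ["patient_id", "drug_code", "start_date", "days_supplied", "daily_dose_mg", "n_units"]
_DRUG_COLS = ["drug_code", "name", "role", "ome_factor"]


@dataclass
class ClaimsBundle:
    """The three raw claims tables plus drug dictionary and code map.

    Tables are pandas DataFrames with the documented column sets; dates
    are ``datetime.date`` objects.  Equality is row-order independent.
    """

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    dictionary: DrugDictionary
    code_map: CodeMap = field(default_factory=default_code_map)

    def __post_init__(self) -> None:
        self.patients = self.patients.reindex(columns=_PATIENT_COLS)
        self.diagnoses = self.diagnoses.reindex(columns=_DX_COLS)
        self.prescriptions = self.prescriptions.reindex(columns=_RX_COLS)
        if self.prescriptions["n_units"].isna().any():
            self.prescriptions["n_units"] = (
                self.prescriptions["n_units"].fillna(1).astype(int)
            )

    # -- validation ----------------------------------------------------

    def validate(self) -> "ClaimsBundle":
        pids = set(self.patients["patient_id"])
        if len(pids) != len(self.patients):
            dup = self.patients["patient_id"][self.patients["patient_id"].duplicated()]
            raise BundleError(f"duplicate patient_id(s): {sorted(set(dup))}")
        for tbl, name in ((self.diagnoses, "diagnoses"), (self.prescriptions, "prescriptions")):
            bad = tbl.loc[~tbl["patient_id"].isin(pids)]
            if len(bad):
                row = bad.index[0]
                raise BundleError(
                    f"{name} row {row}: unknown patient_id {bad['patient_id'].iloc[0]!r}"
                )
        known_drugs = set(self.dictionary)
        bad = self.prescriptions.loc[~self.prescriptions["drug_code"].isin(known_drugs)]
        if len(bad):
            raise BundleError(
                f"prescriptions row {bad.index[0]}: unknown drug_code "
                f"{bad['drug_code'].iloc[0]!r}"
            )
        bad_codes = self.diagnoses.loc[
            ~self.diagnoses["icd10_code"].astype(str).str.match(_ICD10_RE)
        ]
        if len(bad_codes):
            raise BundleError(
                f"diagnoses row {bad_codes.index[0]}: malformed ICD-10 code "
                f"{bad_codes['icd10_code'].iloc[0]!r}"
            )
        if (self.prescriptions["days_supplied"] < 1).any():
            raise BundleError("days_supplied must be >= 1")
        if (self.prescriptions["daily_dose_mg"] < 0).any():
            raise BundleError("daily_dose_mg must be non-negative")
        if (self.prescriptions["n_units"] < 1).any():
            raise BundleError("n_units must be >= 1")
        # no record may fall after the patient's end of data
        eod = self.patients.set_index("patient_id")["end_of_data"]
        rx_eod = self.prescriptions["patient_id"].map(eod)
        if (self.prescriptions["start_date"] > rx_eod).any():
            row = self.prescriptions.index[self.prescriptions["start_date"] > rx_eod][0]
            raise BundleError(f"prescriptions row {row}: start_date after end_of_data")
        return self

    # -- convenience ---------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def canonical(self) -> "ClaimsBundle":
        """Return a copy with deterministically sorted rows (for comparison)."""
        return replace(
            self,
            patients=self.patients.sort_values(_PATIENT_COLS, ignore_index=True),
            diagnoses=self.diagnoses.sort_values(_DX_COLS, ignore_index=True),
            prescriptions=self.prescriptions.sort_values(_RX_COLS, ignore_index=True),
        )

    def equals(self, other: "ClaimsBundle") -> bool:
        a, b = self.canonical(), other.canonical()
        return (
            a.patients.equals(b.patients)
            and a.diagnoses.equals(b.diagnoses)
            and a.prescriptions.equals(b.prescriptions)
            and a.dictionary == b.dictionary
        )

    def prescriptions_for(self, patient_id: str) -> pd.DataFrame:
        return self.prescriptions[self.prescriptions["patient_id"] == patient_id]

    def diagnoses_for(self, patient_id: str) -> pd.DataFrame:
        return self.diagnoses[self.diagnoses["patient_id"] == patient_id]


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------


def _parse_dates(frame: pd.DataFrame, col: str, fname: str) -> None:
    parsed = pd.to_datetime(frame[col], format="%Y-%m-%d", errors="coerce")
    if parsed.isna().any():
        row = frame.index[parsed.isna()][0]
        raise BundleError(f"{fname} row {row}: malformed date {frame[col].iloc[row]!r}")
    frame[col] = parsed.dt.date


def read_bundle(directory: str | Path, code_map: CodeMap | None = None) -> ClaimsBundle:
    """Read and validate a claims bundle from ``directory``.

    Expects ``patients.csv``, ``diagnoses.csv``, ``prescriptions.csv``
    and ``drugs.csv``; an optional ``code_map.json`` overrides the
    default covariate map (the ``code_map`` argument wins over both).
    """
    directory = Path(directory)
    frames = {}
    for fname in ("patients.csv", "diagnoses.csv", "prescriptions.csv", "drugs.csv"):
        path = directory / fname
        if not path.exists():
            raise BundleError(f"missing input file: {fname}")
        frames[fname] = pd.read_csv(path, dtype={"patient_id": str, "drug_code": str,
                                                 "icd10_code": str})

    pat = frames["patients.csv"]
    _parse_dates(pat, "end_of_data", "patients.csv")
    if len(pat):
        pat["birth_year"] = pat["birth_year"].astype(int)

    dx = frames["diagnoses.csv"]
    _parse_dates(dx, "date", "diagnoses.csv")

    rx = frames["prescriptions.csv"]
    _parse_dates(rx, "start_date", "prescriptions.csv")
    if len(rx):
        rx["days_supplied"] = rx["days_supplied"].astype(int)
        rx["daily_dose_mg"] = rx["daily_dose_mg"].astype(float)
        if "n_units" not in rx.columns:
            rx["n_units"] = 1
        rx["n_units"] = rx["n_units"].fillna(1).astype(int)

    drugs = frames["drugs.csv"]
    entries: dict[str, DrugInfo] = {}
    for i, row in drugs.iterrows():
        raw = row.get("ome_factor")
        if pd.isna(raw) or str(raw).strip() in ("", _NC_TOKEN):
            factor = NOT_CONVERTIBLE
        else:
            try:
                factor = float(raw)
            except ValueError as exc:
                raise BundleError(f"drugs.csv row {i}: bad ome_factor {raw!r}") from exc
        entries[str(row["drug_code"])] = DrugInfo(str(row["name"]), str(row["role"]), factor)

    if code_map is None:
        cm_path = directory / "code_map.json"
        if cm_path.exists():
            code_map = CodeMap.from_dict(json.loads(cm_path.read_text()))
        else:
            code_map = default_code_map()

    bundle = ClaimsBundle(pat, dx, rx, DrugDictionary(entries), code_map)
    return bundle.validate()


def write_bundle(bundle: ClaimsBundle, directory: str | Path) -> None:
    """Write the bundle as the four CSV files (plus code_map.json).

    ``read_bundle(write_bundle(b)) == b``; NOT_CONVERTIBLE OME factors
    are serialized as the reserved token ``NC``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    b = bundle.canonical()
    b.patients.to_csv(directory / "patients.csv", index=False)
    b.diagnoses.to_csv(directory / "diagnoses.csv", index=False)
    b.prescriptions.to_csv(directory / "prescriptions.csv", index=False)
    rows = [
        {
            "drug_code": code,
            "name": info.name,
            "role": info.role,
            "ome_factor": _NC_TOKEN if info.ome_factor is NOT_CONVERTIBLE else info.ome_factor,
        }
        for code, info in sorted(bundle.dictionary.items())
    ]
    pd.DataFrame(rows, columns=_DRUG_COLS).to_csv(directory / "drugs.csv", index=False)
    (directory / "code_map.json").write_text(json.dumps(bundle.code_map.to_dict(), indent=1))
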