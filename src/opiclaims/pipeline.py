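"""End-to-end orchestration: bundle -> episodes -> cohort -> tables -> regression.

`CohortStudy` is the top-level modelling object: construct it from a
claims bundle (or via :meth:`CohortStudy.from_synthetic`), call
:meth:`fit`, and read the patient-flow report, the descriptive table,
the selected variables with audit log, the proportional-odds fit and
the rescue table off the returned :class:`CohortStudyResults`.
`run_all` is the file-oriented wrapper the CLI uses.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .claims import ClaimsBundle, read_bundle
from .cohort import (
    CohortLabel,
    GROUP_NAMES,
    Thresholds,
    classify,
    covariate_table,
    descriptive_table,
    format_pct,
)
from .episodes import Episode, build_episodes, select_eligible
from .ordinal import ProportionalOddsModel, ProportionalOddsResults
from .rescue import rescue_rows, rescue_summary
from .selection import SelectionConfig, select_variables
from .synth import SimulationConfig, generate_bundle

logger = logging.getLogger("opiclaims")

__all__ = ["FlowReport", "CohortStudy", "CohortStudyResults", "run_all"]

#: Collinearity pairs mirroring the published manual step-2 choices:
#: metastasis flags overlap, and psychiatric diagnoses proxy their drugs.
DEFAULT_COLLINEAR_PAIRS = (
    ("distant_metastasis", "bone_metastasis"),
    ("dur_TCA", "schizophrenia"),
    ("dur_SSRI", "mood_disorders"),
    ("dur_SNRI", "anxiety"),
)


@dataclass(frozen=True)
class FlowReport:
    """Patient-flow (attrition) counts with dose-calculable percentages."""

    n_eligible: int
    n_dose_calculable: int
    n_control: int
    n_case_i: int
    n_case_ii: int
    n_long_low_dose: int

    def __post_init__(self) -> None:
        groups = self.n_control + self.n_case_i + self.n_case_ii + self.n_long_low_dose
        if groups != self.n_dose_calculable:
            raise ValueError(
                f"group counts ({groups}) do not sum to dose-calculable total "
                f"({self.n_dose_calculable})"
            )
        if self.n_dose_calculable > self.n_eligible:
            raise ValueError("dose-calculable count exceeds eligible count")

    def percentages(self) -> dict[str, float]:
        """Group shares of the dose-calculable total, half-up to one decimal."""
        d = self.n_dose_calculable
        return {
            "control": format_pct(self.n_control, d),
            "case_I": format_pct(self.n_case_i, d),
            "case_II": format_pct(self.n_case_ii, d),
            "long_low_dose": format_pct(self.n_long_low_dose, d),
        }

    def to_text(self) -> str:
        p = self.percentages()
        lines = [
            f"eligible patients              {self.n_eligible}",
            f"  dose calculable              {self.n_dose_calculable}",
            f"    control                    {self.n_control} ({p['control']}%)",
            f"    case I                     {self.n_case_i} ({p['case_I']}%)",
            f"    case II                    {self.n_case_ii} ({p['case_II']}%)",
            f"    long-term low-dose (excl.) {self.n_long_low_dose} ({p['long_low_dose']}%)",
        ]
        return "\n".join(lines)


class CohortStudy:
    """Long-term, high-dose opioid cohort analysis of a claims bundle.

    Parameters
    ----------
    bundle : ClaimsBundle
        Patients, diagnoses, prescriptions, drug dictionary, code map.
    thresholds : Thresholds
        Episode gap and classification cut-offs (30 d / 183 d /
        120 mg/day OME / 730 d by default).
    selection : SelectionConfig
        Two-step variable-selection settings for the regression.
    """

    def __init__(
        self,
        bundle: ClaimsBundle,
        thresholds: Thresholds = Thresholds(),
        selection: SelectionConfig | None = None,
    ):
        self.bundle = bundle
        self.thresholds = thresholds
        self.selection = selection or SelectionConfig(
            collinear_pairs=DEFAULT_COLLINEAR_PAIRS,
            force_include=(
                "large_intestine_anus",
                "osteoarthritis_knee",
                "spinal_stenosis",
                "spondylosis",
                "dur_radiotherapy",
                "dur_chemotherapy",
            ),
        )

    @classmethod
    def from_synthetic(cls, config: SimulationConfig, **kwargs) -> "CohortStudy":
        bundle, truth = generate_bundle(config)
        study = cls(bundle, **kwargs)
        study.ground_truth = truth
        return study

    def fit(self, fit_regression: bool = True) -> "CohortStudyResults":
        bundle, th = self.bundle, self.thresholds
        eligibles = select_eligible(bundle)
        logger.info("stage=eligibility n_patients=%d n_eligible=%d",
                    bundle.n_patients, len(eligibles))

        episodes: dict[str, Episode] = build_episodes(bundle, eligibles, gap_days=th.gap_days)
        labels: dict[str, CohortLabel] = {
            pid: classify(ep, th) for pid, ep in episodes.items()
        }
        logger.info("stage=episodes n_episodes=%d", len(episodes))

        flow = FlowReport(
            n_eligible=len(eligibles),
            n_dose_calculable=sum(
                1 for l in labels.values()
                if l.excluded_reason != "dose_not_calculable"
            ),
            n_control=sum(1 for l in labels.values() if l.group == 0),
            n_case_i=sum(1 for l in labels.values() if l.group == 1),
            n_case_ii=sum(1 for l in labels.values() if l.group == 2),
            n_long_low_dose=sum(
                1 for l in labels.values() if l.excluded_reason == "long_low_dose"
            ),
        )

        covariates = covariate_table(bundle, eligibles, episodes, labels)
        logger.info("stage=covariates n_rows=%d", len(covariates))

        table1 = descriptive_table(covariates) if len(covariates) else pd.DataFrame()
        selected, audit = select_variables(table1, self.selection) if len(table1) else ([], [])

        regression: ProportionalOddsResults | None = None
        if fit_regression and selected:
            kept = covariates[covariates["group"].notna()]
            usable = [
                v for v in selected
                if v in kept.columns and kept[v].nunique() > 1
            ]
            dropped = [v for v in selected if v not in usable]
            for v in dropped:
                audit.append(
                    {"variable": v, "action": "fit:dropped", "reason": "constant in analysis set"}
                )
            if kept["group"].nunique() == 3 and usable:
                model = ProportionalOddsModel.from_dataframe(
                    kept.assign(group=kept["group"].astype(int)), "group", usable
                )
                regression = model.fit()
                logger.info("stage=regression n_vars=%d llf=%.3f", len(usable), regression.llf)

        grouped = {pid: l.group for pid, l in labels.items() if l.group is not None}
        table3 = (
            rescue_summary(rescue_rows(bundle, episodes, grouped)) if grouped else pd.DataFrame()
        )

        return CohortStudyResults(
            study=self,
            flow=flow,
            episodes=episodes,
            labels=labels,
            covariates=covariates,
            table1=table1,
            selected_variables=selected,
            audit_log=audit,
            regression=regression,
            table3=table3,
        )


@dataclass
class CohortStudyResults:
    """Everything the analysis produces, plus formatting helpers."""

    study: CohortStudy
    flow: FlowReport
    episodes: dict[str, Episode]
    labels: dict[str, CohortLabel]
    covariates: pd.DataFrame
    table1: pd.DataFrame
    selected_variables: list[str]
    audit_log: list[dict]
    regression: ProportionalOddsResults | None
    table3: pd.DataFrame

    def config_stamp(self) -> dict:
        th = asdict(self.study.thresholds)
        sel = asdict(self.study.selection)
        blob = json.dumps({"thresholds": th, "selection": sel}, sort_keys=True, default=str)
        return {
            "thresholds": th,
            "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        }

    def summary(self) -> str:
        parts = [
            "Long-term, high-dose opioid prescription cohort analysis",
            "=" * 56,
            self.flow.to_text(),
            "",
            f"variables selected for regression: {', '.join(self.selected_variables) or '(none)'}",
        ]
        if self.regression is not None:
            parts += ["", self.regression.summary().to_string(index=False,
                                                              float_format=lambda v: f"{v:.3f}")]
        return "\n".join(parts)

    def table2(self) -> pd.DataFrame:
        if self.regression is None:
            return pd.DataFrame()
        return self.regression.summary()

    def plot_dose_distribution(self, ax=None):
        """Histogram of mean daily OME by cohort group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        kept = self.covariates[self.covariates["group"].notna()]
        for g, name in GROUP_NAMES.items():
            vals = kept.loc[kept["group"] == g, "mean_daily_ome"]
            if len(vals):
                ax.hist(vals, bins=40, alpha=0.5, label=name, density=True)
        ax.set_xlabel("mean daily OME (mg/day)")
        ax.set_ylabel("density")
        ax.legend()
        return ax


def run_all(
    bundle_dir: str | Path | None,
    out_dir: str | Path,
    thresholds: Thresholds = Thresholds(),
    selection: SelectionConfig | None = None,
    sim_config: SimulationConfig | None = None,
) -> CohortStudyResults:
    """File-oriented pipeline: read (or synthesize) a bundle, analyse, write tables.

    Writes flow_report.txt, table1.csv, table2.csv, table3.csv,
    covariates.csv, episodes.csv and audit_log.json into ``out_dir``,
    each stamped with the configuration hash.  Fully deterministic given
    the bundle (or the simulation seed).
    """
    if (bundle_dir is None) == (sim_config is None):
        raise ValueError("provide exactly one of bundle_dir or sim_config")
    if sim_config is not None:
        study = CohortStudy.from_synthetic(sim_config, thresholds=thresholds,
                                           selection=selection)
    else:
        study = CohortStudy(read_bundle(bundle_dir), thresholds=thresholds,
                            selection=selection)
    results = study.fit()

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = results.config_stamp()
    (out / "flow_report.txt").write_text(
        results.flow.to_text() + f"\n\nconfig_hash: {stamp['config_hash']}\n"
    )
    ep_rows = [
        {
            "patient_id": pid,
            "index_date": ep.index_date.isoformat(),
            "end_date": ep.end_date.isoformat(),
            "duration_days": ep.duration_days,
            "total_ome_mg": ep.total_ome_mg,
            "mean_daily_ome": ep.mean_daily_ome,
            "dose_calculable": ep.dose_calculable,
        }
        for pid, ep in sorted(results.episodes.items())
    ]
    pd.DataFrame(ep_rows).to_csv(out / "episodes.csv", index=False)
    results.covariates.to_csv(out / "covariates.csv", index=False)
    results.table1.to_csv(out / "table1.csv", index=False)
    results.table2().to_csv(out / "table2.csv", index=False)
    results.table3.to_csv(out / "table3.csv", index=False)
    (out / "audit_log.json").write_text(
        json.dumps({"stamp": stamp, "audit": results.audit_log}, indent=1)
    )
    return results
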