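"""Two-step explanatory-variable selection for the ordinal regression.

Step 1 filters the descriptive-table factors: continuous variables enter
when significant (p < alpha) in *both* case-vs-control comparisons;
categorical variables additionally require an incidence of at least
``min_incidence`` in the control or either case group (the alternative
"union" reading — significant OR prevalent — is available via
``step1_mode``).  Step 2 applies declared collinear pairs (keeping the
first-listed member), forced inclusions justified on clinical grounds,
and forced exclusions.  Every decision is written to an audit log.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["SelectionConfig", "select_variables"]


@dataclass(frozen=True)
class SelectionConfig:
    alpha: float = 0.05
    min_incidence: float = 0.05
    step1_mode: str = "intersection"  # or "union"
    force_include: tuple[str, ...] = ()
    force_exclude: tuple[str, ...] = ()
    #: declared collinear pairs (kept, dropped)
    collinear_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.step1_mode not in ("intersection", "union"):
            raise ValueError("step1_mode must be 'intersection' or 'union'")


def select_variables(
    descriptive: pd.DataFrame, config: SelectionConfig = SelectionConfig()
) -> tuple[list[str], list[dict]]:
    """Return the ordered explanatory-variable list and an audit log.

    ``descriptive`` is the output of
    :func:`opiclaims.cohort.descriptive_table` (columns ``variable``,
    ``type``, ``p_case_I``, ``p_case_II`` and, for categorical rows,
    ``pct_*`` per group).
    """
    audit: list[dict] = []
    selected: list[str] = []

    def log(variable: str, action: str, reason: str) -> None:
        audit.append({"variable": variable, "action": action, "reason": reason})

    for _, row in descriptive.iterrows():
        var = row["variable"]
        p1, p2 = row.get("p_case_I"), row.get("p_case_II")
        significant = (
            pd.notna(p1) and pd.notna(p2) and p1 < config.alpha and p2 < config.alpha
        )
        if row["type"] == "categorical":
            incidences = [
                row.get(f"pct_{g}", float("nan")) / 100.0
                for g in ("control", "case_I", "case_II")
            ]
            prevalent = any(
                pd.notna(v) and v >= config.min_incidence for v in incidences
            )
            if config.step1_mode == "intersection":
                keep = significant and prevalent
                why = (
                    f"significant in both comparisons (p={p1:.3g}, {p2:.3g}) and "
                    f"incidence >= {config.min_incidence:.0%}"
                    if keep
                    else "not significant in both comparisons"
                    if not significant
                    else f"incidence below {config.min_incidence:.0%} in all groups"
                )
            else:
                keep = significant or prevalent
                why = "significant or prevalent" if keep else "neither significant nor prevalent"
        else:
            keep = significant
            why = (
                f"significant in both comparisons (p={p1:.3g}, {p2:.3g})"
                if keep
                else "not significant in both comparisons"
            )
        log(var, "step1:selected" if keep else "step1:dropped", why)
        if keep:
            selected.append(var)

    # step 2 -----------------------------------------------------------
    for kept, dropped in config.collinear_pairs:
        if dropped in selected and kept in selected:
            selected.remove(dropped)
            log(dropped, "step2:dropped", f"declared collinear with {kept}")
    for var in config.force_exclude:
        if var in selected:
            selected.remove(var)
            log(var, "step2:dropped", "forced exclusion")
    for var in config.force_include:
        if var not in selected:
            selected.append(var)
            log(var, "step2:added", "forced: clinical perspective")

    return selected, audit
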