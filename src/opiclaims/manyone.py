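"""Many-to-one multiple comparisons: Dunnett (parametric) and Steel (rank).

Both procedures compare each of k treatment groups against a single
shared control with familywise two-sided error control.  Because every
contrast shares the control sample, the contrast statistics are
positively correlated; the adjusted p-value for contrast i is

    p_i = 1 - P(|T_1| <= |t_i|, ..., |T_k| <= |t_i|)

under the joint null distribution — central multivariate t for Dunnett
(pooled-variance t statistics), multivariate normal for Steel
(tie-corrected standardized rank sums).  The correlation between
contrasts i and j is sqrt(lam_i * lam_j) with lam_i = n_i / (n_i + n_0).

Steel additionally offers an exact-style permutation mode that permutes
the pooled observations across all groups and uses the permutation
distribution of the maximum absolute standardized rank statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["Contrast", "ManyOneResult", "dunnett_test", "steel_test"]

_CDF_SEED = 180_451  # fixed QMC stream for the multivariate-t integrator


@dataclass(frozen=True)
class Contrast:
    group: str
    statistic: float
    p_unadjusted: float
    p_adjusted: float


@dataclass(frozen=True)
class ManyOneResult:
    method: str
    contrasts: tuple[Contrast, ...]
    df: float | None = None

    @property
    def by_group(self) -> dict[str, Contrast]:
        return {c.group: c for c in self.contrasts}

    def p_values(self) -> dict[str, float]:
        return {c.group: c.p_adjusted for c in self.contrasts}


def _contrast_correlation(n0: int, ns: np.ndarray) -> np.ndarray:
    lam = ns / (ns + n0)
    r = np.sqrt(np.outer(lam, lam))
    np.fill_diagonal(r, 1.0)
    return r


def _rectangle_prob_t(c: float, corr: np.ndarray, df: float) -> float:
    """P(max_j |T_j| <= c) for central multivariate t with unit scales."""
    if c <= 0:
        return 0.0
    k = corr.shape[0]
    if k == 1:
        return float(stats.t.cdf(c, df) - stats.t.cdf(-c, df))
    mvt = stats.multivariate_t(shape=corr, df=df)
    return float(
        np.clip(
            mvt.cdf(
                np.full(k, c),
                lower_limit=np.full(k, -c),
                random_state=np.random.default_rng(_CDF_SEED),
            ),
            0.0,
            1.0,
        )
    )


def _rectangle_prob_norm(c: float, corr: np.ndarray) -> float:
    if c <= 0:
        return 0.0
    k = corr.shape[0]
    if k == 1:
        return float(stats.norm.cdf(c) - stats.norm.cdf(-c))
    mvn = stats.multivariate_normal(cov=corr, allow_singular=True)
    return float(np.clip(mvn.cdf(np.full(k, c), lower_limit=np.full(k, -c)), 0.0, 1.0))


def dunnett_test(control: np.ndarray, cases: dict[str, np.ndarray]) -> ManyOneResult:
    """Dunnett's many-to-one test for continuous outcomes.

    Pooled-variance two-sided t statistics for each case group against
    the control, familywise-adjusted via the equicoordinate rectangle of
    the central multivariate t with the sample-size-determined contrast
    correlation.  Requires >= 2 observations per group.  A zero pooled
    variance yields p = 1 with a warning.
    """
    control = np.asarray(control, dtype=float)
    arrays = {name: np.asarray(v, dtype=float) for name, v in cases.items()}
    if len(control) < 2 or any(len(v) < 2 for v in arrays.values()):
        raise ValueError("each group needs at least 2 observations")

    names = list(arrays)
    ns = np.array([len(arrays[g]) for g in names])
    n0 = len(control)
    n_total = n0 + ns.sum()
    df = n_total - (len(names) + 1)

    ss = np.var(control, ddof=1) * (n0 - 1) + sum(
        np.var(arrays[g], ddof=1) * (len(arrays[g]) - 1) for g in names
    )
    s2 = ss / df
    corr = _contrast_correlation(n0, ns)

    contrasts = []
    for g, n_g in zip(names, ns):
        if s2 == 0:
            warnings.warn("zero pooled variance; p-values set to 1", stacklevel=2)
            contrasts.append(Contrast(g, 0.0, 1.0, 1.0))
            continue
        t = (arrays[g].mean() - control.mean()) / np.sqrt(s2 * (1 / n_g + 1 / n0))
        p_un = 2 * stats.t.sf(abs(t), df)
        p_adj = 1.0 - _rectangle_prob_t(abs(t), corr, df)
        contrasts.append(Contrast(g, float(t), float(min(p_un, 1.0)), float(min(max(p_adj, p_un), 1.0))))
    return ManyOneResult("dunnett", tuple(contrasts), df=float(df))


def _steel_statistics(control: np.ndarray, arrays: dict[str, np.ndarray]) -> dict[str, float]:
    """Tie-corrected standardized rank-sum statistic per case group."""
    zs = {}
    n0 = len(control)
    for g, x in arrays.items():
        n1 = len(x)
        pooled = np.concatenate([control, x])
        ranks = stats.rankdata(pooled)  # midranks
        w = ranks[n0:].sum()
        n = n0 + n1
        e = n1 * (n + 1) / 2.0
        var = n0 * n1 / (n * (n - 1)) * ((ranks**2).sum() - n * (n + 1) ** 2 / 4.0)
        zs[g] = 0.0 if var <= 0 else (w - e) / np.sqrt(var)
    return zs


def steel_test(
    control: np.ndarray,
    cases: dict[str, np.ndarray],
    method: str = "asymptotic",
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
) -> ManyOneResult:
    """Steel's many-to-one rank test (handles binary 0/1 data via midranks).

    Each case group is compared with the control by a Wilcoxon rank-sum
    statistic with midranks for ties, standardized with the
    tie-corrected variance; the familywise adjustment integrates the
    equicoordinate rectangle of the correlated bivariate (generally
    k-variate) normal.  ``method="permutation"`` instead permutes the
    pooled sample and uses the null distribution of max_j |Z_j|.
    A pooled-constant sample yields p = 1 with a warning.
    """
    control = np.asarray(control, dtype=float)
    arrays = {name: np.asarray(v, dtype=float) for name, v in cases.items()}
    if len(control) < 2 or any(len(v) < 2 for v in arrays.values()):
        raise ValueError("each group needs at least 2 observations")

    names = list(arrays)
    ns = np.array([len(arrays[g]) for g in names])
    n0 = len(control)
    pooled_all = np.concatenate([control] + [arrays[g] for g in names])
    constant = np.ptp(pooled_all) == 0
    if constant:
        warnings.warn("constant pooled sample; p-values set to 1", stacklevel=2)
        return ManyOneResult(
            "steel", tuple(Contrast(g, 0.0, 1.0, 1.0) for g in names)
        )

    zs = _steel_statistics(control, arrays)
    corr = _contrast_correlation(n0, ns)

    if method == "permutation":
        rng = np.random.default_rng(rng)
        sizes = [n0] + [len(arrays[g]) for g in names]
        splits = np.cumsum(sizes)[:-1]
        max_abs = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = rng.permutation(pooled_all)
            parts = np.split(perm, splits)
            zb = _steel_statistics(parts[0], dict(zip(names, parts[1:])))
            max_abs[b] = max(abs(v) for v in zb.values())
        contrasts = []
        for g in names:
            z = zs[g]
            # unadjusted p stays asymptotic; only the joint adjustment is permuted
            p_un = float(min(2 * stats.norm.sf(abs(z)), 1.0))
            p_adj = float((np.sum(max_abs >= abs(z) - 1e-12) + 1) / (n_permutations + 1))
            contrasts.append(Contrast(g, float(z), p_un, min(max(p_adj, p_un), 1.0)))
        return ManyOneResult("steel-permutation", tuple(contrasts))

    contrasts = []
    for g in names:
        z = zs[g]
        p_un = float(min(2 * stats.norm.sf(abs(z)), 1.0))
        p_adj = 1.0 - _rectangle_prob_norm(abs(z), corr)
        contrasts.append(Contrast(g, float(z), p_un, float(min(max(p_adj, p_un), 1.0))))
    return ManyOneResult("steel", tuple(contrasts))
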