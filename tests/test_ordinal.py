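"""Proportional-odds model: closed forms, cross-checks, recovery, symmetry."""

import numpy as np
import pandas as pd
import pytest

from opiclaims.ordinal import ConvergenceError, ProportionalOddsModel
from opiclaims.synth import generate_regression_dataset


def logit(p):
    return np.log(p / (1 - p))


def test_intercept_only_equals_empirical_cumulative_logits():
    y = np.array([0] * 70 + [1] * 20 + [2] * 10)
    res = ProportionalOddsModel(y).fit()
    assert res.intercepts[0] == pytest.approx(logit(0.30), abs=1e-8)
    assert res.intercepts[1] == pytest.approx(logit(0.10), abs=1e-8)


def test_matches_statsmodels_ordered_model():
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    x, y, _ = generate_regression_dataset(
        3000, {"a": 0.7, "b": -0.4}, (-1.0, -2.0), seed=3
    )
    ours = ProportionalOddsModel.from_dataframe(
        pd.concat([x, y], axis=1), "group", ["a", "b"]
    ).fit()
    sm_fit = OrderedModel(y, x, distr="logit").fit(method="bfgs", disp=False)
    # statsmodels parameterizes P(Y <= k) = logistic(c_k - x'b): betas agree
    # directly, cutpoints with the opposite sign.
    assert ours.beta == pytest.approx(sm_fit.params[["a", "b"]].to_numpy(), abs=1e-4)
    sm_cuts = np.array(
        [sm_fit.params.iloc[2], sm_fit.params.iloc[2] + np.exp(sm_fit.params.iloc[3])]
    )
    assert ours.intercepts == pytest.approx(-sm_cuts, abs=1e-4)
    assert ours.bse[2:] == pytest.approx(sm_fit.bse[["a", "b"]].to_numpy(), rel=1e-3)
    assert ours.llf == pytest.approx(sm_fit.llf, abs=1e-6)


def test_outcome_reversal_symmetry():
    x, y, _ = generate_regression_dataset(2000, {"a": 0.5}, (-0.5, -1.5), seed=9)
    data = pd.concat([x, y], axis=1)
    fwd = ProportionalOddsModel.from_dataframe(data, "group", ["a"]).fit()
    rev = ProportionalOddsModel.from_dataframe(
        data.assign(group=2 - data["group"]), "group", ["a"]
    ).fit()
    assert rev.beta == pytest.approx(-fwd.beta, abs=1e-6)
    assert rev.intercepts == pytest.approx(
        [-fwd.intercepts[1], -fwd.intercepts[0]], abs=1e-6
    )


def test_parameter_recovery_moderate_n():
    x, y, _ = generate_regression_dataset(
        20000, {"risk": np.log(2)}, (-1.5, -2.5), seed=21
    )
    res = ProportionalOddsModel.from_dataframe(
        pd.concat([x, y], axis=1), "group", ["risk"]
    ).fit()
    assert res.beta[0] == pytest.approx(np.log(2), abs=3 * res.bse[2])
    lo, hi = np.exp(res.conf_int()[2])
    assert lo <= res.odds_ratios[0] <= hi


def test_loglikelihood_monotone_and_gradient_small():
    x, y, _ = generate_regression_dataset(1500, {"a": 0.8, "b": 0.1}, (-1.0, -2.0), seed=2)
    res = ProportionalOddsModel.from_dataframe(
        pd.concat([x, y], axis=1), "group", ["a", "b"]
    ).fit()
    lls = [t[1] for t in res.trace]
    assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))
    assert res.grad_norm < 1e-6


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError, match="level"):
        ProportionalOddsModel(np.array([0, 1, 1, 0]))  # only two levels
    y = np.array([0, 1, 2, 0, 1, 2])
    with pytest.raises(ValueError, match="constant"):
        ProportionalOddsModel(y, np.ones((6, 1)))


def test_separation_raises_diagnostic_error():
    y = np.array([0] * 20 + [1] * 5 + [2] * 20)
    x = (y > 0).astype(float).reshape(-1, 1)  # perfectly predicts Y >= 1
    with pytest.raises(ConvergenceError) as err:
        ProportionalOddsModel(y, x).fit(maxiter=30)
    assert len(err.value.trace) > 0


def test_regression_dataset_marginals_and_validation():
    x, y, params = generate_regression_dataset(
        200_000, {}, (logit(0.2), logit(0.05)), seed=4
    )
    assert abs((y >= 1).mean() - 0.2) < 0.005
    assert abs((y >= 2).mean() - 0.05) < 0.003
    x1, y1, _ = generate_regression_dataset(1, {"a": 0.0}, (-1.0, -2.0), seed=0)
    assert len(x1) == len(y1) == 1
    with pytest.raises(ValueError, match="decreasing"):
        generate_regression_dataset(10, {}, (-2.0, -1.0), seed=0)


def test_regression_dataset_cumulative_odds_ratio():
    """Monte-Carlo check of the generator against its own model: one binary
    covariate with beta = log 2 gives an empirical cumulative odds ratio
    near 2."""
    x, y, _ = generate_regression_dataset(
        50_000, {"a": np.log(2)}, (-1.0, -2.0), seed=8
    )
    a = x["a"].to_numpy() == 1
    p1, p0 = (y[a] >= 1).mean(), (y[~a] >= 1).mean()
    or_hat = (p1 / (1 - p1)) / (p0 / (1 - p0))
    assert or_hat == pytest.approx(2.0, abs=0.15)
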