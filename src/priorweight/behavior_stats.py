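"""Model-free regression and group-level parameter prediction tests.

The model-free analysis regresses, per subject, the relative-distance
score y = |R - mu_g| - |R - mu_bar| (positive when the response sits
closer to the prior mean than to the observation mean) on an
expected-variability indicator (high = 1) and the raw observed
variability v_g, then tests the per-subject coefficients against zero at
the group level with one-sample t-tests (df = n_subjects - 1).

The model-based analysis tests the four directional predictions on the
fitted full-model parameters: v_bar_H > v_bar_L, a_g > 0,
omega_H > omega_L, b_g > 0.  All tests are two-tailed at alpha .05.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .fitting import FitResult
from .observer_model import ModelVariant, ObserverParams

__all__ = [
    "relative_distance_dv",
    "subject_regression",
    "group_ttest",
    "group_regression_test",
    "prediction_tests",
]

ALPHA = 0.05


def relative_distance_dv(r, mu_g, mu_bar):
    """Relative-distance score ``y = |R - mu_g| - |R - mu_bar|`` (litres)."""
    r = np.asarray(r, dtype=float)
    mu_g = np.asarray(mu_g, dtype=float)
    mu_bar = np.asarray(mu_bar, dtype=float)
    return np.abs(r - mu_g) - np.abs(r - mu_bar)


def subject_regression(trials: pd.DataFrame, responses: pd.DataFrame) -> pd.Series:
    """Per-subject OLS of y on [intercept, high-variability indicator, v_g].

    Observed variability enters raw (litres); sign conclusions are
    invariant to its scaling.  Raises on rank deficiency.
    """
    if len(trials) != len(responses):
        raise ValueError("trials and responses are misaligned")
    if len(trials) < 3:
        raise ValueError("need at least 3 trials for a 3-parameter regression")
    y = relative_distance_dv(
        responses["R"].to_numpy(),
        trials["mu_g"].to_numpy(),
        trials["mu_bar"].to_numpy(),
    )
    expvar = (trials["var_cond"] == "high").to_numpy(dtype=float)
    x = sm.add_constant(
        np.column_stack([expvar, trials["v_g"].to_numpy(dtype=float)]),
        has_constant="add",
    )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, x).fit()
    return pd.Series(fit.params, index=["intercept", "beta_expvar", "beta_vg"])


def group_ttest(values: Sequence[float], null_value: float = 0.0) -> tuple[float, int, float]:
    """One-sample two-tailed t-test; returns (t, df, p) with df = n - 1."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if np.std(values, ddof=1) == 0:
        raise ValueError("zero variance; t undefined")
    t, p = stats.ttest_1samp(values, null_value)
    return float(t), values.size - 1, float(p)


def group_regression_test(cohort) -> pd.DataFrame:
    """Run the per-subject regression over a cohort and test each
    coefficient against zero at the group level."""
    betas = pd.DataFrame([
        subject_regression(sub.trials, sub.responses) for sub in cohort
    ])
    rows = []
    for name in betas.columns:
        t, df, p = group_ttest(betas[name].to_numpy())
        rows.append({
            "coefficient": name,
            "mean": float(betas[name].mean()),
            "t": t,
            "df": df,
            "p": p,
            "significant": p < ALPHA,
        })
    return pd.DataFrame(rows)


_CONTRASTS = (
    ("v_bar_H - v_bar_L", lambda p: p.v_bar_H - p.v_bar_L),
    ("a_g", lambda p: p.a_g),
    ("omega_H - omega_L", lambda p: p.omega_H - p.omega_L),
    ("b_g", lambda p: p.b_g),
)


def prediction_tests(fits: Sequence[FitResult | ObserverParams]) -> pd.DataFrame:
    """The four directional group tests on fitted full-model parameters.

    Paired contrasts (v_bar_H - v_bar_L, omega_H - omega_L) and one-sample
    tests (a_g, b_g) against zero; all predicted positive.  Accepts
    FitResults (must be full-model) or raw parameter sets.
    """
    params: list[ObserverParams] = []
    for f in fits:
        if isinstance(f, FitResult):
            if f.variant is not ModelVariant.FULL:
                raise ValueError("prediction tests require full-model fits")
            params.append(f.params)
        else:
            params.append(f)
    if len(params) < 2:
        raise ValueError("need at least 2 subjects (df = n - 1 > 0)")
    rows = []
    for label, extract in _CONTRASTS:
        values = np.array([extract(p) for p in params])
        t, df, p = group_ttest(values)
        rows.append({
            "contrast": label,
            "mean": float(values.mean()),
            "t": t,
            "df": df,
            "p": p,
            "significant": p < ALPHA,
            "direction_ok": bool(values.mean() > 0),
        })
    return pd.DataFrame(rows)
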