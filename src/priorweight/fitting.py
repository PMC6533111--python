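"""Maximum-likelihood fitting and model comparison for the observer family.

Each subject is fitted independently by multi-start bounded Powell
minimisation of the negative log-likelihood; the six model variants share
one likelihood through the variant parameter maps.  Comparison uses BIC
(k ln n + 2 NLL, per subject, summed across subjects) and McFadden's
pseudo-r-squared against the fixed-Gaussian baseline.  A brute-force grid
oracle and a split-half reliability analysis support validation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import pearsonr

from .observer_model import (
    BaselineParams,
    ModelVariant,
    ObserverParams,
    weight,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "ZScoreTransform",
    "zscore_vg",
    "negative_log_likelihood",
    "fit_subject",
    "grid_mle_oracle",
    "bic",
    "mcfadden_pseudo_r2",
    "compare_models",
    "split_half_reliability",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

# penalty used inside the optimizer when the SD-positivity constraint is
# violated: large, finite, and sloped back toward the feasible region so
# Powell line searches recover.  The public NLL reports +inf instead.
_PENALTY_BASE = 1e10
_PENALTY_SLOPE = 1e6


@dataclass(frozen=True)
class ZScoreTransform:
    """Stored z-scoring map so the same transform can be reapplied."""

    mean: float
    sd: float

    def __call__(self, v_g) -> np.ndarray:
        return (np.asarray(v_g, dtype=float) - self.mean) / self.sd


def zscore_vg(trials: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, ZScoreTransform]:
    """Z-score observed variability over a subject's full trial set.

    Pooled over all sessions and conditions; population SD (ddof 0), so the
    output has mean exactly 0 and SD exactly 1 and two distinct values map
    to exactly +/-1.  Returns the transformed values and the stored map.
    """
    v_g = trials["v_g"].to_numpy() if isinstance(trials, pd.DataFrame) else np.asarray(trials, dtype=float)
    if v_g.size < 2:
        raise ValueError("need at least two trials to z-score v_g")
    sd = float(np.std(v_g))
    if sd == 0:
        raise ValueError("v_g is constant; z-scoring undefined")
    tf = ZScoreTransform(float(np.mean(v_g)), sd)
    return tf(v_g), tf


@dataclass(frozen=True)
class _TrialArrays:
    """Preextracted per-trial arrays for fast likelihood evaluation."""

    mu_bar: np.ndarray
    mu_g: np.ndarray
    vg_prime: np.ndarray
    high: np.ndarray
    r: np.ndarray

    @classmethod
    def build(cls, trials: pd.DataFrame, responses: pd.DataFrame) -> "_TrialArrays":
        if len(trials) != len(responses):
            raise ValueError("trials and responses are misaligned")
        if not np.array_equal(
            trials[["session_index", "trial_index"]].to_numpy(),
            responses[["session_index", "trial_index"]].to_numpy(),
        ):
            raise ValueError("trials and responses index different trials")
        vg_prime, _ = zscore_vg(trials)
        return cls(
            mu_bar=trials["mu_bar"].to_numpy(dtype=float),
            mu_g=trials["mu_g"].to_numpy(dtype=float),
            vg_prime=vg_prime,
            high=(trials["var_cond"] == "high").to_numpy(),
            r=responses["R"].to_numpy(dtype=float),
        )


def _observer_nll(p: ObserverParams, arr: _TrialArrays, penalized: bool) -> float:
    v_bar = np.where(arr.high, p.v_bar_H, p.v_bar_L)
    omega = np.where(arr.high, p.omega_H, p.omega_L)
    s = omega + p.b_g * arr.vg_prime
    s_min = s.min()
    if s_min <= 0:
        if penalized:
            return _PENALTY_BASE + _PENALTY_SLOPE * (1.0 - s_min)
        return float("inf")
    w = weight(v_bar, p.a_g, arr.vg_prime)
    mu_hat = arr.mu_bar + w * (arr.mu_g - arr.mu_bar)
    z = (arr.r - mu_hat) / s
    return float(np.sum(0.5 * _LOG_2PI + np.log(s) + 0.5 * z * z))


def _baseline_nll(p: BaselineParams, arr: _TrialArrays, penalized: bool) -> float:
    if p.s <= 0:
        return _PENALTY_BASE + _PENALTY_SLOPE * (1.0 - p.s) if penalized else float("inf")
    z = (arr.r - p.m) / p.s
    return float(np.sum(0.5 * _LOG_2PI + np.log(p.s) + 0.5 * z * z))


def negative_log_likelihood(
    params: ObserverParams | BaselineParams,
    variant: ModelVariant,
    trials: pd.DataFrame,
    responses: pd.DataFrame,
) -> float:
    """Summed negative Gaussian log-likelihood of the responses.

    Returns +inf if the parameter vector yields a non-positive response SD
    on any trial of this dataset (the SD-positivity constraint).  The
    baseline variant ignores trial structure entirely.
    """
    arr = _TrialArrays.build(trials, responses)
    if variant is ModelVariant.BASELINE:
        if not isinstance(params, BaselineParams):
            raise TypeError("baseline variant requires BaselineParams")
        return _baseline_nll(params, arr, penalized=False)
    p = variant.to_params(variant.from_params(params))
    return _observer_nll(p, arr, penalized=False)


# per-parameter multi-start sampling boxes and optimizer bounds, by the
# leading character class of the free-parameter name
_START_BOXES = {
    "v_bar": (-4.0, 4.0),
    "a_g": (-2.0, 2.0),
    "omega": (0.2, 6.0),
    "b_g": (-2.0, 2.0),
    "m": (10.0, 25.0),
    "s": (0.2, 8.0),
}
_BOUNDS = {
    "v_bar": (-10.0, 10.0),
    "a_g": (-5.0, 5.0),
    "omega": (1e-2, 15.0),
    "b_g": (-5.0, 5.0),
    "m": (5.0, 30.0),
    "s": (1e-2, 15.0),
}


def _param_class(name: str) -> str:
    for prefix in ("v_bar", "omega", "a_g", "b_g"):
        if name.startswith(prefix):
            return prefix
    return name  # "m" or "s"


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings: multi-start count, seed and tolerances."""

    n_starts: int = 20
    seed: int = 0
    xtol: float = 1e-6
    ftol: float = 1e-6
    maxiter: int = 2000


@dataclass
class FitResult:
    """One subject x variant maximum-likelihood estimate."""

    variant: ModelVariant
    params: ObserverParams | BaselineParams
    x: np.ndarray
    nll: float
    n_trials: int
    k: int
    bic: float
    n_starts: int
    best_start_index: int
    converged: bool
    seed: int

    def free_dict(self) -> dict[str, float]:
        return dict(zip(self.variant.free_names, self.x))


def bic(nll: float, k: int, n_trials: int) -> float:
    """Bayesian Information Criterion, ``k * ln(n) + 2 * NLL`` (lower wins)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return k * float(np.log(n_trials)) + 2.0 * nll


def mcfadden_pseudo_r2(nll_model: float, nll_baseline: float) -> float:
    """McFadden's pseudo-r-squared, ``1 - NLL_model / NLL_baseline``.

    Quantifies fit improvement over the fixed-Gaussian baseline; 0 for the
    baseline itself, approaching 1 for a perfect model.  A model worse than
    baseline yields a negative value (returned as-is with a warning).
    """
    if nll_baseline <= 0:
        raise ValueError("baseline NLL must be positive")
    value = 1.0 - nll_model / nll_baseline
    if value < 0:
        import warnings

        warnings.warn("model fits worse than baseline (negative pseudo-r2)")
    return value


def fit_subject(
    trials: pd.DataFrame,
    responses: pd.DataFrame,
    variant: ModelVariant = ModelVariant.FULL,
    fit_config: FitConfig = FitConfig(),
) -> FitResult:
    """Multi-start bounded Powell MLE of one variant on one subject.

    Starts are drawn from fixed uniform boxes; the best (lowest-NLL) start
    wins, ties broken by the lowest start index.  Deterministic given
    (data, variant, fit_config).
    """
    if len(trials) < variant.k + 1:
        raise ValueError("need more trials than free parameters")
    arr = _TrialArrays.build(trials, responses)
    names = variant.free_names

    if variant is ModelVariant.BASELINE:
        def objective(x):
            return _baseline_nll(BaselineParams(x[0], max(x[1], 1e-12)), arr, penalized=True)
    else:
        def objective(x):
            return _observer_nll(variant.to_params(x), arr, penalized=True)

    rng = np.random.default_rng(
        np.random.SeedSequence(
            entropy=fit_config.seed, spawn_key=(list(ModelVariant).index(variant),)
        )
    )
    lo = np.array([_START_BOXES[_param_class(n)][0] for n in names])
    hi = np.array([_START_BOXES[_param_class(n)][1] for n in names])
    bounds = [_BOUNDS[_param_class(n)] for n in names]

    best = None
    failures = []
    for start_index in range(fit_config.n_starts):
        x0 = rng.uniform(lo, hi)
        # nudge starts into the feasible region
        for _ in range(20):
            if objective(x0) < _PENALTY_BASE:
                break
            x0 = rng.uniform(lo, hi)
        try:
            res = minimize(
                objective,
                x0,
                method="Powell",
                bounds=bounds,
                options={
                    "xtol": fit_config.xtol,
                    "ftol": fit_config.ftol,
                    "maxiter": fit_config.maxiter,
                },
            )
        except Exception as exc:  # pragma: no cover - optimizer failure path
            failures.append((start_index, repr(exc)))
            continue
        if not np.isfinite(res.fun) or res.fun >= _PENALTY_BASE:
            failures.append((start_index, "infeasible optimum"))
            continue
        if best is None or res.fun < best[1].fun - 1e-12:
            best = (start_index, res)
    if best is None:
        raise RuntimeError(f"all optimizer starts failed: {failures}")

    start_index, res = best
    # tight simplex polish of the winning start; Powell alone can stall a
    # few tenths of a nat short of the optimum on this likelihood
    polish = minimize(
        objective,
        res.x,
        method="Nelder-Mead",
        bounds=bounds,
        options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 20_000, "maxfev": 20_000},
    )
    if np.isfinite(polish.fun) and polish.fun <= res.fun:
        res = polish
    x = np.asarray(res.x, dtype=float)
    if variant is ModelVariant.BASELINE:
        params: ObserverParams | BaselineParams = BaselineParams(*x)
        nll = _baseline_nll(params, arr, penalized=False)
    else:
        params = variant.to_params(x)
        nll = _observer_nll(params, arr, penalized=False)
    return FitResult(
        variant=variant,
        params=params,
        x=x,
        nll=nll,
        n_trials=len(trials),
        k=variant.k,
        bic=bic(nll, variant.k, len(trials)),
        n_starts=fit_config.n_starts,
        best_start_index=start_index,
        converged=bool(res.success),
        seed=fit_config.seed,
    )


def grid_mle_oracle(
    trials: pd.DataFrame,
    responses: pd.DataFrame,
    variant: ModelVariant,
    grid_spec: dict[str, np.ndarray],
    max_points: int = 1_000_000,
) -> tuple[np.ndarray, float]:
    """Exhaustive grid search over the variant's free parameters.

    ``grid_spec`` maps every free-parameter name to a 1-D array of values
    (singletons pin a parameter).  Test-only brute-force oracle; refuses
    grids beyond ``max_points``.
    """
    names = variant.free_names
    missing = set(names) - set(grid_spec)
    if missing:
        raise ValueError(f"grid_spec missing parameters: {sorted(missing)}")
    axes = [np.atleast_1d(np.asarray(grid_spec[n], dtype=float)) for n in names]
    n_points = int(np.prod([len(a) for a in axes]))
    if n_points > max_points:
        raise ValueError(f"grid of {n_points} points exceeds limit {max_points}")
    arr = _TrialArrays.build(trials, responses)
    best_x, best_nll = None, float("inf")
    for combo in itertools.product(*axes):
        x = np.array(combo)
        if variant is ModelVariant.BASELINE:
            nll = _baseline_nll(BaselineParams(*x), arr, penalized=False)
        else:
            nll = _observer_nll(variant.to_params(x), arr, penalized=False)
        if nll < best_nll:
            best_x, best_nll = x, nll
    return best_x, best_nll


@dataclass
class ComparisonTable:
    """Cohort-level model comparison: summed NLL/BIC, pseudo-r2, winners."""

    table: pd.DataFrame
    fits: dict[str, list[FitResult]] = field(repr=False, default_factory=dict)


def compare_models(
    cohort,
    variants: tuple[ModelVariant, ...] = tuple(ModelVariant),
    fit_config: FitConfig = FitConfig(),
) -> ComparisonTable:
    """Fit every subject under every variant and tabulate the comparison.

    Reports per-variant summed NLL, pseudo-r2 (from summed NLLs against
    the baseline, when present), summed BIC, and for how many subjects the
    variant attains the lowest BIC.  Per-subject BIC ties are broken toward
    the simpler model (fewer free parameters).
    """
    subjects = list(cohort)
    if not subjects:
        raise ValueError("empty cohort")
    fits: dict[str, list[FitResult]] = {v.value: [] for v in variants}
    for sub in subjects:
        for v in variants:
            fits[v.value].append(fit_subject(sub.trials, sub.responses, v, fit_config))

    rows = []
    nll_base = (
        sum(f.nll for f in fits[ModelVariant.BASELINE.value])
        if ModelVariant.BASELINE in variants
        else None
    )
    # per-subject winner: lowest BIC, ties toward fewer parameters
    win_counts = {v.value: 0 for v in variants}
    for i in range(len(subjects)):
        ranked = sorted(
            (fits[v.value][i] for v in variants),
            key=lambda f: (round(f.bic, 9), f.k),
        )
        win_counts[ranked[0].variant.value] += 1

    for v in variants:
        nll_sum = sum(f.nll for f in fits[v.value])
        bic_sum = sum(f.bic for f in fits[v.value])
        rows.append({
            "variant": v.value,
            "k": v.k,
            "nll": nll_sum,
            "pseudo_r2": mcfadden_pseudo_r2(nll_sum, nll_base) if nll_base else float("nan"),
            "bic": bic_sum,
            "n_best": win_counts[v.value],
        })
    table = pd.DataFrame(rows).set_index("variant")
    return ComparisonTable(table=table, fits=fits)


def split_half_reliability(
    cohort,
    variant: ModelVariant = ModelVariant.FULL,
    fit_config: FitConfig = FitConfig(),
    rng: np.random.Generator | None = None,
    *,
    split: bool = True,
) -> pd.DataFrame:
    """Split-half reliability of the fitted parameters across subjects.

    Each subject's trials are randomly halved (seeded); the variant is
    fitted separately per half (v_g z-scored within each half), and each
    free parameter's two half-estimates are correlated across subjects
    (Pearson r, two-tailed p).  ``split=False`` fits the full set twice —
    a degenerate identity check used in tests.
    """
    subjects = list(cohort)
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for a cross-subject correlation")
    if rng is None:
        rng = np.random.default_rng(fit_config.seed)
    half_a: list[np.ndarray] = []
    half_b: list[np.ndarray] = []
    for sub in subjects:
        n = len(sub.trials)
        if split:
            if n < 2 * (variant.k + 1):
                raise ValueError("too few trials per half to fit the variant")
            perm = rng.permutation(n)
            idx_a, idx_b = np.sort(perm[: n // 2]), np.sort(perm[n // 2:])
        else:
            idx_a = idx_b = np.arange(n)
        for idx, store in ((idx_a, half_a), (idx_b, half_b)):
            t = sub.trials.iloc[idx].reset_index(drop=True)
            r = sub.responses.iloc[idx].reset_index(drop=True)
            store.append(fit_subject(t, r, variant, fit_config).x)
    a = np.vstack(half_a)
    b = np.vstack(half_b)
    rows = []
    for j, name in enumerate(variant.free_names):
        if np.std(a[:, j]) == 0 or np.std(b[:, j]) == 0:
            r_val, p_val = float("nan"), float("nan")
        else:
            r_val, p_val = pearsonr(a[:, j], b[:, j])
        rows.append({"parameter": name, "r": r_val, "p": p_val})
    return pd.DataFrame(rows)
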