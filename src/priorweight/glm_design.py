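"""Model-derived fMRI parametric-modulator event tables.

Builds the event/modulator tables a neuroimaging GLM tool would consume:

* GLM-1 — zero-duration ("stick") regressors at gauge onset, one per
  expected-variability condition, each modulated by the prediction error
  PE = |mu_bar - mu_g| (mean-centred within condition), the raw observed
  variability v_g (deliberately NOT centred: the conditions differ in mean
  v_g by design, and centring within condition would bias the high-vs-low
  contrast), and RT as a centred nuisance modulator.
* GLM-2 — a single gauge-onset regressor modulated by the linear weight
  expression v_bar(condition) + a_g * vg' computed from group-mean fitted
  parameters, plus centred RT.
* Feedback — a stick regressor at feedback onset modulated by the outcome
  prediction error |feedback - R| (centred).

Estimation (HRF convolution, design matrices) is the downstream tool's
job and out of scope here.  Tables export as tab-separated text with
columns onset / duration / trial_type plus one column per modulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import zscore_vg
from .observer_model import precision_weighted_pe, weight

__all__ = [
    "EventTable",
    "build_glm1_events",
    "build_glm2_events",
    "build_feedback_events",
    "binned_modulator_table",
]

_BASE_COLUMNS = ["onset", "duration", "trial_type"]


@dataclass
class EventTable:
    """Event rows plus metadata on how each modulator was centred.

    ``centring`` maps modulator name to ``"within_condition"``,
    ``"overall"`` or ``None`` (raw).  ``flags`` collects degeneracy notes
    (e.g. a constant modulator).
    """

    events: pd.DataFrame
    centring: dict[str, str | None] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def modulators(self) -> list[str]:
        return [c for c in self.events.columns if c not in _BASE_COLUMNS]

    def check_centring(self, tol: float = 1e-9) -> None:
        """Verify the declared centring state against the emitted values."""
        for name, mode in self.centring.items():
            col = self.events[name]
            if mode == "overall":
                if abs(col.mean()) > tol:
                    raise AssertionError(f"{name} declared centred but mean={col.mean()}")
            elif mode == "within_condition":
                for cond, grp in self.events.groupby("trial_type"):
                    if abs(grp[name].mean()) > tol:
                        raise AssertionError(
                            f"{name} not centred within condition {cond}"
                        )

    def to_tsv(self, path) -> None:
        self.events.to_csv(Path(path), sep="\t", index=False)


def _centre(values: np.ndarray) -> np.ndarray:
    return values - values.mean()


def _require_rt(responses: pd.DataFrame) -> np.ndarray:
    if "rt" not in responses.columns or responses["rt"].isna().any():
        raise ValueError("responses must carry an RT for every trial")
    return responses["rt"].to_numpy(dtype=float)


def _check_aligned(trials: pd.DataFrame, responses: pd.DataFrame) -> None:
    if len(trials) != len(responses) or not np.array_equal(
        trials[["session_index", "trial_index"]].to_numpy(),
        responses[["session_index", "trial_index"]].to_numpy(),
    ):
        raise ValueError("trials and responses are misaligned")


def build_glm1_events(trials: pd.DataFrame, responses: pd.DataFrame) -> EventTable:
    """GLM-1: condition stick regressors with PE, raw v_g and RT modulators."""
    _check_aligned(trials, responses)
    rt = _require_rt(responses)
    cond = np.where(trials["var_cond"] == "high", "high_expvar", "low_expvar")
    df = pd.DataFrame({
        "onset": trials["onset"].to_numpy(dtype=float),
        "duration": 0.0,
        "trial_type": cond,
        "pe": trials["pe"].to_numpy(dtype=float),
        "vg": trials["v_g"].to_numpy(dtype=float),
        "rt": rt,
    })
    for name in ("pe", "rt"):
        df[name] = df.groupby("trial_type")[name].transform(lambda v: v - v.mean())
    table = EventTable(
        events=df,
        centring={"pe": "within_condition", "vg": None, "rt": "within_condition"},
    )
    table.check_centring()
    return table


def build_glm2_events(
    trials: pd.DataFrame,
    group_params: dict[str, float],
    responses: pd.DataFrame | None = None,
) -> EventTable:
    """GLM-2: one gauge-onset regressor modulated by v_bar + a_g * vg'.

    ``group_params`` must supply ``v_bar_L``, ``v_bar_H`` and ``a_g`` —
    typically the means of the per-subject full-model fits, applied
    identically to all subjects.  vg' uses the subject's own z-scoring.
    The expression is exported raw (uncentred): like raw v_g in GLM-1 it
    differs between conditions by design.  An auxiliary ``pe_w`` column
    carries the implied precision-weighted prediction error.
    """
    missing = {"v_bar_L", "v_bar_H", "a_g"} - set(group_params)
    if missing:
        raise ValueError(f"group_params missing: {sorted(missing)}")
    vg_prime, _ = zscore_vg(trials)
    high = (trials["var_cond"] == "high").to_numpy()
    v_bar = np.where(high, group_params["v_bar_H"], group_params["v_bar_L"])
    expression = v_bar + group_params["a_g"] * vg_prime
    w = weight(v_bar, group_params["a_g"], vg_prime)
    pe_w = precision_weighted_pe(
        w, trials["mu_g"].to_numpy(dtype=float), trials["mu_bar"].to_numpy(dtype=float)
    )
    df = pd.DataFrame({
        "onset": trials["onset"].to_numpy(dtype=float),
        "duration": 0.0,
        "trial_type": "gauges",
        "weight_lin": expression,
        "pe_w": pe_w,
    })
    centring: dict[str, str | None] = {"weight_lin": None, "pe_w": None}
    flags: list[str] = []
    if responses is not None:
        _check_aligned(trials, responses)
        df["rt"] = _centre(_require_rt(responses))
        centring["rt"] = "overall"
    if np.ptp(expression) == 0:
        flags.append("degenerate: weight expression is constant over trials")
    return EventTable(events=df, centring=centring, flags=flags)


def build_feedback_events(
    responses: pd.DataFrame,
    feedback_values,
    feedback_delay: float = 0.3,
) -> EventTable:
    """Feedback-time stick regressor modulated by |feedback - R| (centred).

    Feedback appears ``feedback_delay`` seconds after the response is
    finalised (gauge onset + RT).
    """
    feedback = np.asarray(feedback_values, dtype=float)
    if len(feedback) != len(responses):
        raise ValueError("feedback and responses are misaligned")
    rt = _require_rt(responses)
    outcome_pe = np.abs(feedback - responses["R"].to_numpy(dtype=float))
    flags = []
    if np.ptp(outcome_pe) == 0:
        flags.append("degenerate: outcome PE constant; centred modulator all zero")
    df = pd.DataFrame({
        "onset": responses["onset"].to_numpy(dtype=float) + rt + feedback_delay,
        "duration": 0.0,
        "trial_type": "feedback",
        "outcome_pe": _centre(outcome_pe),
    })
    table = EventTable(events=df, centring={"outcome_pe": "overall"}, flags=flags)
    table.check_centring()
    return table


def binned_modulator_table(
    trials: pd.DataFrame, modulator_name: str, n_bins: int = 3
) -> EventTable:
    """Split trials into equal-count bins of a modulator for display GLMs.

    Bins are formed by modulator rank (stable sort, ties broken by trial
    order); each bin becomes its own stick-regressor condition.  Bin sizes
    differ by at most one when the trial count is not divisible.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_bins > len(trials):
        raise ValueError("more bins than trials")
    values = trials[modulator_name].to_numpy(dtype=float)
    order = np.argsort(values, kind="stable")
    bin_of = np.empty(len(values), dtype=int)
    flags = []
    for i, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = i
    sizes = np.bincount(bin_of, minlength=n_bins)
    if sizes.max() != sizes.min():
        flags.append(f"unequal bin sizes {sizes.tolist()} (n not divisible by bins)")
    df = pd.DataFrame({
        "onset": trials["onset"].to_numpy(dtype=float),
        "duration": 0.0,
        "trial_type": [f"{modulator_name}_bin{i + 1}" for i in bin_of],
        modulator_name: values,
    })
    return EventTable(events=df, centring={modulator_name: None}, flags=flags)
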