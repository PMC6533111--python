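"""Generative simulator of the fuel-gauge estimation task.

Participants estimate the fuel in a motorbike tank (an integer between 10
and 25 litres) from cued prior information and two noisy gauge readings.
Per trial the true amount ``mu`` is drawn from a Gaussian around the cued
expected value (15 or 20 L, SD 3); the two gauge readings are drawn around
``mu`` with SD 4 (low expected variability) or 7 (high).  ``mu`` and the
readings are rounded to the nearest integer and clipped to [10, 25].
Trials are organised in blocks of 5 sharing the same prior cue, with a
seeded balanced pseudo-random block order; the default experiment is four
sessions of 120 trials (480 total, perfectly balanced over the four
expected-value x expected-variability conditions).

Synthetic responses are drawn from any observer-model variant, and a
cohort generator packages per-subject trials, responses and true
generating parameters for recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .observer_model import (
    BaselineParams,
    ModelVariant,
    ObserverParams,
    posterior_mean,
    response_sd,
    weight,
)

__all__ = [
    "TaskConfig",
    "SubjectData",
    "Cohort",
    "generate_session",
    "generate_experiment",
    "simulate_responses",
    "generate_cohort",
    "sample_observer_params",
    "summarize_trials",
    "round_half_up",
    "write_table",
    "read_table",
]

VAR_CONDITIONS = ("low", "high")

TRIAL_COLUMNS = [
    "session_index", "block_index", "trial_index",
    "mu_bar", "var_cond",
    "mu_true_raw", "mu_true",
    "g1_raw", "g1", "g2_raw", "g2",
    "mu_g", "v_g", "pe", "onset",
]

RESPONSE_COLUMNS = ["session_index", "trial_index", "onset", "R", "R_cont", "rt"]


def round_half_up(x):
    """Round to the nearest integer, halves away from zero.

    Matches everyday rounding of instrument readings (all task quantities
    are positive, so this equals round-half-up); numpy's banker's rounding
    would map 0.5 offsets down for even targets.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class TaskConfig:
    """Design constants of the estimation task.

    Defaults reproduce the study design: 4 sessions x 120 trials in blocks
    of 5, expected values {15, 20} litres with prior SD 3, gauge SD 4 (low
    expected variability) or 7 (high), responses on the integer scale
    [10, 25].  ``trial_interval`` spaces nominal onsets (seconds) purely so
    event export is well-formed.
    """

    n_sessions: int = 4
    trials_per_session: int = 120
    block_len: int = 5
    expected_values: tuple[int, ...] = (15, 20)
    prior_sd: float = 3.0
    obs_sd_low: float = 4.0
    obs_sd_high: float = 7.0
    response_min: int = 10
    response_max: int = 25
    trial_interval: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_session % self.block_len != 0:
            raise ValueError("trials_per_session must be divisible by block_len")
        n_blocks = self.trials_per_session // self.block_len
        n_cond = len(self.expected_values) * len(VAR_CONDITIONS)
        if n_blocks % n_cond != 0:
            raise ValueError(
                f"{n_blocks} blocks per session cannot be balanced over "
                f"{n_cond} conditions"
            )
        if not self.response_min < self.response_max:
            raise ValueError("response_min must be below response_max")
        if min(self.prior_sd, self.obs_sd_low, self.obs_sd_high) <= 0:
            raise ValueError("all SDs must be positive")

    @property
    def blocks_per_session(self) -> int:
        return self.trials_per_session // self.block_len

    @property
    def conditions(self) -> list[tuple[int, str]]:
        return [(v, c) for v in self.expected_values for c in VAR_CONDITIONS]

    def obs_sd(self, var_cond: str) -> float:
        return self.obs_sd_low if var_cond == "low" else self.obs_sd_high

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["expected_values"] = list(self.expected_values)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "expected_values" in d:
            d["expected_values"] = tuple(d["expected_values"])
        return cls(**d)


def _session_rng(config: TaskConfig, session_index: int) -> np.random.Generator:
    # deterministic per-session stream derived from the master seed
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(session_index,))
    )


def generate_session(
    config: TaskConfig,
    session_index: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate one session of trials as a tidy DataFrame.

    Block order is a seeded permutation of a balanced multiset of the
    expected-value x expected-variability conditions; within a block all
    trials share the prior cue.  Raw (pre-rounding) draws are retained
    alongside the rounded, clipped integer values.
    """
    if rng is None:
        rng = _session_rng(config, session_index)
    n_cond = len(config.conditions)
    reps = config.blocks_per_session // n_cond
    block_conds = [c for c in config.conditions for _ in range(reps)]
    order = rng.permutation(len(block_conds))
    n = config.trials_per_session

    mu_bar = np.empty(n)
    var_cond = np.empty(n, dtype=object)
    block_index = np.repeat(np.arange(config.blocks_per_session), config.block_len)
    for b, j in enumerate(order):
        ev, vc = block_conds[j]
        sl = slice(b * config.block_len, (b + 1) * config.block_len)
        mu_bar[sl] = ev
        var_cond[sl] = vc

    obs_sd = np.where(var_cond == "low", config.obs_sd_low, config.obs_sd_high)
    mu_true_raw = rng.normal(mu_bar, config.prior_sd)
    g1_raw = rng.normal(mu_true_raw, obs_sd)
    g2_raw = rng.normal(mu_true_raw, obs_sd)

    lo, hi = config.response_min, config.response_max
    mu_true = np.clip(round_half_up(mu_true_raw), lo, hi)
    g1 = np.clip(round_half_up(g1_raw), lo, hi)
    g2 = np.clip(round_half_up(g2_raw), lo, hi)

    mu_g = (g1 + g2) / 2.0
    v_g = np.abs(g1 - g2)
    pe = np.abs(mu_bar - mu_g)
    onset = np.arange(n) * config.trial_interval

    return pd.DataFrame({
        "session_index": session_index,
        "block_index": block_index,
        "trial_index": np.arange(n),
        "mu_bar": mu_bar.astype(int),
        "var_cond": var_cond,
        "mu_true_raw": mu_true_raw,
        "mu_true": mu_true.astype(int),
        "g1_raw": g1_raw,
        "g1": g1.astype(int),
        "g2_raw": g2_raw,
        "g2": g2.astype(int),
        "mu_g": mu_g,
        "v_g": v_g,
        "pe": pe,
        "onset": onset,
    })[TRIAL_COLUMNS]


def generate_experiment(config: TaskConfig) -> pd.DataFrame:
    """Concatenate all sessions, each with an independent sub-seeded stream."""
    sessions = [generate_session(config, i) for i in range(config.n_sessions)]
    return pd.concat(sessions, ignore_index=True)


def simulate_responses(
    trials: pd.DataFrame,
    params: ObserverParams | BaselineParams,
    variant: ModelVariant = ModelVariant.FULL,
    rng: np.random.Generator | None = None,
    *,
    rt_scale: float = 2.0,
    rt_sigma: float = 0.3,
    response_min: int = 10,
    response_max: int = 25,
) -> pd.DataFrame:
    """Draw integer responses for every trial from an observer variant.

    The posterior mean and response SD are computed with vg' z-scored over
    the supplied trial list; the continuous Gaussian draw is rounded to the
    nearest integer and clipped to the response scale, since the button
    interface only permits integers.  RTs are nuisance plumbing, drawn from
    a seeded log-normal around ``rt_scale`` seconds.
    """
    from .fitting import zscore_vg  # local import: fitting depends on observer_model only

    if rng is None:
        rng = np.random.default_rng(0)
    n = len(trials)
    if isinstance(params, BaselineParams) or variant is ModelVariant.BASELINE:
        mu_hat = np.full(n, params.m)
        s = np.full(n, params.s)
    else:
        # round-trip through the variant so ties/zeros are imposed
        full = variant.to_params(variant.from_params(params))
        vg_prime, _ = zscore_vg(trials)
        high = (trials["var_cond"] == "high").to_numpy()
        v_bar = np.where(high, full.v_bar_H, full.v_bar_L)
        omega = np.where(high, full.omega_H, full.omega_L)
        w = weight(v_bar, full.a_g, vg_prime)
        mu_hat = posterior_mean(w, trials["mu_g"].to_numpy(), trials["mu_bar"].to_numpy())
        s = response_sd(omega, full.b_g, vg_prime)
        if np.any(s <= 0):
            raise ValueError(
                "response SD non-positive on some trial; parameters violate "
                "the SD-positivity constraint for this trial set"
            )
    r_cont = rng.normal(mu_hat, s)
    r = np.clip(round_half_up(r_cont), response_min, response_max).astype(int)
    rt = rt_scale * rng.lognormal(mean=0.0, sigma=rt_sigma, size=n)
    return pd.DataFrame({
        "session_index": trials["session_index"].to_numpy(),
        "trial_index": trials["trial_index"].to_numpy(),
        "onset": trials["onset"].to_numpy(),
        "R": r,
        "R_cont": r_cont,
        "rt": rt,
    })


def sample_observer_params(rng: np.random.Generator) -> ObserverParams:
    """Draw plausible per-subject generating parameters.

    Centred on the qualitative group pattern — v_bar_H > v_bar_L (less
    weight on high-variability gauges), a_g > 0, omega_H > omega_L > 0,
    b_g > 0 — with between-subject spread.  The v_bar centres correspond
    roughly to the normative precision-ratio weights for gauge SDs 4 and 7
    against a prior SD of 3 (w* ~ 0.53 and 0.27).  Draws are truncated at
    two SDs: empirical per-subject parameter clouds are bounded, and the
    unbounded tail would produce near-deterministic observers (w ~ 1 with
    sub-litre response noise) for whom a continuous response density is a
    poor description of integer button presses.
    """

    def trunc(mean, sd):
        return float(np.clip(rng.normal(mean, sd), mean - 2 * sd, mean + 2 * sd))

    return ObserverParams(
        v_bar_L=trunc(-0.1, 0.5),
        v_bar_H=trunc(1.0, 0.5),
        a_g=trunc(0.5, 0.25),
        omega_L=max(trunc(1.5, 0.4), 0.5),
        omega_H=max(trunc(2.5, 0.6), 0.7),
        b_g=trunc(0.4, 0.2),
    )


@dataclass
class SubjectData:
    """One synthetic participant: trials, responses and generating truth."""

    subject_index: int
    trials: pd.DataFrame
    responses: pd.DataFrame
    true_params: ObserverParams | BaselineParams
    seed: int


@dataclass
class Cohort:
    subjects: list[SubjectData] = field(default_factory=list)
    n_resampled: int = 0

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)


def generate_cohort(
    config: TaskConfig,
    param_sampler: Callable[[np.random.Generator], ObserverParams] = sample_observer_params,
    n_subjects: int = 33,
    variant: ModelVariant = ModelVariant.FULL,
) -> Cohort:
    """Simulate a cohort for parameter/model-recovery studies.

    Each subject gets an independently seeded experiment and response draw;
    sampled parameter sets that violate SD-positivity on the subject's
    trials are discarded and resampled (counted in ``n_resampled``).
    """
    root = np.random.SeedSequence(entropy=config.seed, spawn_key=(977,))
    cohort = Cohort()
    for i in range(n_subjects):
        sub_ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(977, i))
        sub_seed = int(sub_ss.generate_state(1)[0] % (2**31))
        trials = generate_experiment(replace(config, seed=sub_seed))
        rng = np.random.default_rng(sub_ss)
        for _attempt in range(100):
            params = param_sampler(rng)
            try:
                responses = simulate_responses(
                    trials, params, variant, rng,
                    response_min=config.response_min,
                    response_max=config.response_max,
                )
                break
            except ValueError:
                cohort.n_resampled += 1
        else:
            raise RuntimeError("param_sampler produced no valid parameters in 100 draws")
        cohort.subjects.append(SubjectData(i, trials, responses, params, sub_seed))
    _ = root  # reserved: root stream kept for future cohort-level draws
    return cohort


def summarize_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-condition validation summary of the generative statistics.

    Reports trial counts, pre-rounding sample SDs of the true fuel draw
    around the cued mean and of the gauge draws around the true fuel, and
    the mean observed disagreement v_g.  SDs are NaN-flagged when a cell
    has fewer than two trials.
    """
    if len(trials) == 0:
        raise ValueError("cannot summarize an empty trial list")

    def _sd(x):
        return float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")

    rows = []
    for (mu_bar, vc), grp in trials.groupby(["mu_bar", "var_cond"], sort=True):
        gauge_dev = np.concatenate([
            grp["g1_raw"] - grp["mu_true_raw"],
            grp["g2_raw"] - grp["mu_true_raw"],
        ])
        rows.append({
            "mu_bar": mu_bar,
            "var_cond": vc,
            "n_trials": len(grp),
            "sd_mu_raw": _sd(grp["mu_true_raw"] - grp["mu_bar"]),
            "sd_gauge_raw": _sd(gauge_dev),
            "mean_v_g": float(grp["v_g"].mean()),
        })
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a trial or response table as tab-separated text."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
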