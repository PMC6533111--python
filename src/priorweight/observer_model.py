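"""Sigmoid-weighted observer model for estimation under uncertainty.

A participant estimates a continuous magnitude (fuel litres) from a cued
prior mean ``mu_bar`` and two noisy gauge readings summarised by their mean
``mu_g`` and disagreement ``v_g = |g1 - g2|``.  The observer forms a
posterior point estimate as a weighted average

    mu_hat = w * mu_g + (1 - w) * mu_bar,

where the weight on the observations is a logistic function of the cued
(expected) variability and the z-scored observed variability vg':

    w = 1 / (1 + exp(v_bar + a_g * vg')).

Larger ``v_bar`` or (for ``a_g > 0``) larger observed disagreement pushes
``w`` toward zero, i.e. toward relying on the prior.  The overt integer
response is modelled as a Gaussian draw around ``mu_hat`` with standard
deviation ``omega_bar + b_g * vg'``, so response stochasticity can itself
grow with expected and observed variability.

All functions here are pure and vectorised over numpy arrays; no I/O.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import expit

__all__ = [
    "ObserverParams",
    "BaselineParams",
    "ModelVariant",
    "weight",
    "posterior_mean",
    "response_sd",
    "response_log_density",
    "precision_weighted_pe",
    "optimal_weight_reference",
]

# canonical ordering of the full model's free parameters
FULL_PARAM_NAMES = ("v_bar_L", "v_bar_H", "a_g", "omega_L", "omega_H", "b_g")


@dataclass(frozen=True)
class ObserverParams:
    """Six free parameters of the full observer model.

    v_bar_L, v_bar_H
        Expected-variability offsets in the sigmoid exponent (dimensionless)
        for low- and high-expected-variability trials.
    a_g
        Effect of z-scored observed variability on the exponent
        (dimensionless per z-unit).
    omega_L, omega_H
        Response-SD intercepts (litres) per expected-variability condition;
        must be positive.
    b_g
        Effect of z-scored observed variability on the response SD
        (litres per z-unit).
    """

    v_bar_L: float
    v_bar_H: float
    a_g: float
    omega_L: float
    omega_H: float
    b_g: float

    def __post_init__(self) -> None:
        if not (self.omega_L > 0 and self.omega_H > 0):
            raise ValueError("omega_L and omega_H must be positive")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FULL_PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, x) -> "ObserverParams":
        x = np.asarray(x, dtype=float)
        if x.shape != (6,):
            raise ValueError("expected a 6-vector")
        return cls(*x)


@dataclass(frozen=True)
class BaselineParams:
    """Baseline model: responses drawn from a fixed Gaussian N(m, s^2)."""

    m: float
    s: float

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError("baseline SD s must be positive")

    def to_vector(self) -> np.ndarray:
        return np.array([self.m, self.s], dtype=float)


class ModelVariant(str, Enum):
    """The six-model family: the full model, four single-constraint
    reductions, and a fixed-Gaussian baseline."""

    FULL = "full"
    TIED_VBAR = "tied_vbar"    # v_bar_L == v_bar_H
    ZERO_AG = "zero_ag"        # a_g == 0
    TIED_OMEGA = "tied_omega"  # omega_L == omega_H
    ZERO_BG = "zero_bg"        # b_g == 0
    BASELINE = "baseline"      # fixed mean and SD, ignores trial structure

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.free_names)

    @property
    def free_names(self) -> tuple[str, ...]:
        return _FREE_NAMES[self]

    def to_params(self, x) -> ObserverParams | BaselineParams:
        """Map a free-parameter vector into the full parameterization.

        Tied/zeroed entries are expanded so every observer variant shares
        one likelihood implementation.
        """
        x = np.asarray(x, dtype=float)
        if x.shape != (self.k,):
            raise ValueError(f"{self.value} expects a {self.k}-vector, got {x.shape}")
        if self is ModelVariant.FULL:
            return ObserverParams(*x)
        if self is ModelVariant.TIED_VBAR:
            v, a, oL, oH, b = x
            return ObserverParams(v, v, a, oL, oH, b)
        if self is ModelVariant.ZERO_AG:
            vL, vH, oL, oH, b = x
            return ObserverParams(vL, vH, 0.0, oL, oH, b)
        if self is ModelVariant.TIED_OMEGA:
            vL, vH, a, o, b = x
            return ObserverParams(vL, vH, a, o, o, b)
        if self is ModelVariant.ZERO_BG:
            vL, vH, a, oL, oH = x
            return ObserverParams(vL, vH, a, oL, oH, 0.0)
        return BaselineParams(*x)

    def from_params(self, params: ObserverParams | BaselineParams) -> np.ndarray:
        """Extract this variant's free vector from full parameters."""
        if self is ModelVariant.BASELINE:
            if not isinstance(params, BaselineParams):
                raise TypeError("baseline variant requires BaselineParams")
            return params.to_vector()
        if not isinstance(params, ObserverParams):
            raise TypeError("observer variants require ObserverParams")
        p = params
        if self is ModelVariant.FULL:
            return p.to_vector()
        if self is ModelVariant.TIED_VBAR:
            return np.array([p.v_bar_L, p.a_g, p.omega_L, p.omega_H, p.b_g])
        if self is ModelVariant.ZERO_AG:
            return np.array([p.v_bar_L, p.v_bar_H, p.omega_L, p.omega_H, p.b_g])
        if self is ModelVariant.TIED_OMEGA:
            return np.array([p.v_bar_L, p.v_bar_H, p.a_g, p.omega_L, p.b_g])
        return np.array([p.v_bar_L, p.v_bar_H, p.a_g, p.omega_L, p.omega_H])


_FREE_NAMES: dict[ModelVariant, tuple[str, ...]] = {
    ModelVariant.FULL: FULL_PARAM_NAMES,
    ModelVariant.TIED_VBAR: ("v_bar", "a_g", "omega_L", "omega_H", "b_g"),
    ModelVariant.ZERO_AG: ("v_bar_L", "v_bar_H", "omega_L", "omega_H", "b_g"),
    ModelVariant.TIED_OMEGA: ("v_bar_L", "v_bar_H", "a_g", "omega", "b_g"),
    ModelVariant.ZERO_BG: ("v_bar_L", "v_bar_H", "a_g", "omega_L", "omega_H"),
    ModelVariant.BASELINE: ("m", "s"),
}


def _check_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def weight(v_bar, a_g, vg_prime):
    """Weight on the observation mean, ``w = 1 / (1 + exp(v_bar + a_g*vg'))``.

    Strictly in (0, 1) and strictly decreasing in the exponent.  Evaluated
    through the logistic ``expit(-exponent)``, which is branch-free and does
    not overflow for large |exponent| (it saturates in float64 beyond ~±37).
    """
    v_bar = _check_finite("v_bar", v_bar)
    a_g = _check_finite("a_g", a_g)
    vg_prime = _check_finite("vg_prime", vg_prime)
    return expit(-(v_bar + a_g * vg_prime))


def posterior_mean(w, mu_g, mu_bar):
    """Posterior point estimate ``mu_hat = w*mu_g + (1-w)*mu_bar`` (litres).

    Always lies between the prior mean and the observation mean, inclusive.
    """
    w = np.asarray(w, dtype=float)
    if np.any((w < 0) | (w > 1)):
        raise ValueError("weight w must lie in [0, 1]")
    mu_g = np.asarray(mu_g, dtype=float)
    mu_bar = np.asarray(mu_bar, dtype=float)
    return w * mu_g + (1.0 - w) * mu_bar


def response_sd(omega_bar, b_g, vg_prime):
    """Response SD ``omega_bar + b_g * vg'`` (litres).

    May be non-positive for inadmissible parameters; callers must treat
    ``s <= 0`` as a constraint violation (this function does not raise).
    """
    omega_bar = _check_finite("omega_bar", omega_bar)
    b_g = _check_finite("b_g", b_g)
    vg_prime = _check_finite("vg_prime", vg_prime)
    return omega_bar + b_g * vg_prime


def response_log_density(r, mu_hat, s):
    """Gaussian log-density of a response: ``R ~ N(mu_hat, s^2)``.

    The density is evaluated continuously at the (integer) response; no
    truncation at the response bounds and no integer binning is applied.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("response SD must be positive")
    r = np.asarray(r, dtype=float)
    mu_hat = np.asarray(mu_hat, dtype=float)
    z = (r - mu_hat) / s
    return -0.5 * np.log(2.0 * np.pi) - np.log(s) - 0.5 * z * z


def precision_weighted_pe(w, mu_g, mu_bar):
    """Precision-weighted prediction error ``|w * (mu_g - mu_bar)|`` (litres).

    The magnitude of the belief update, a surprise measure; never exceeds
    the raw prediction error ``|mu_bar - mu_g|``.
    """
    w = np.asarray(w, dtype=float)
    mu_g = np.asarray(mu_g, dtype=float)
    mu_bar = np.asarray(mu_bar, dtype=float)
    return np.abs(w * (mu_g - mu_bar))


def optimal_weight_reference(prior_sd, obs_sd, n_observations=2):
    """Normative precision-ratio weight for the mean of n Gaussian readings.

    ``w* = (n/obs_sd^2) / (n/obs_sd^2 + 1/prior_sd^2)`` — the weight an
    ideal Bayesian observer with a conjugate Gaussian prior would place on
    the observation mean.  Serves as a validation baseline for the fitted
    sigmoid weights: a higher observation SD yields a lower w*.
    """
    prior_sd = np.asarray(prior_sd, dtype=float)
    obs_sd = np.asarray(obs_sd, dtype=float)
    if np.any(prior_sd <= 0) or np.any(obs_sd <= 0):
        raise ValueError("standard deviations must be positive")
    if n_observations < 1:
        raise ValueError("n_observations must be >= 1")
    obs_prec = n_observations / obs_sd**2
    prior_prec = 1.0 / prior_sd**2
    return obs_prec / (obs_prec + prior_prec)
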