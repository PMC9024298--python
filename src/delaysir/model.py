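"""Core model: parameters, Crowley–Martin incidence, thresholds, equilibria.

The model is an SIR system on population fractions (S + I + R = 1) with

* vertical transmission — a fraction ``q = 1 - p`` of offspring of infected
  parents are born infected;
* vaccination of susceptibles at proportion ``m``, with immunity that wanes
  after a fixed delay ``omega``: individuals vaccinated at ``t - omega``
  re-enter the susceptible class at ``t``, discounted by the survival
  probability ``exp(-b*omega)``;
* a Crowley–Martin incidence ``beta*S*I / (1 + a1*S + a2*I + a1*a2*S*I)``;
* optionally, multiplicative white noise of intensity ``sigma`` on the
  transmission coefficient.

This module holds every closed-form quantity of the analysis: the bilinear
and Crowley–Martin basic reproduction numbers (``r0_bilinear``, ``r0_cm``),
the noise-corrected stochastic threshold (``r0_stochastic``), the invariant
region cap ``b/(b + m(1 - e^{-b omega}))``, the disease-free and endemic
equilibria, the almost-sure exponential decay bound ``lambda_I`` under the
extinction conditions, and the persistence-in-the-mean lower bound ``I*``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "ModelParameters",
    "EpidemicState",
    "EquilibriumSet",
    "ThresholdReport",
    "crowley_martin_denominator",
    "incidence_rate",
    "delta_cap",
    "r0_bilinear",
    "r0_cm",
    "r0_stochastic",
    "equilibria",
    "extinction_conditions",
    "persistence_bound",
    "classify_regime",
]


@dataclass(frozen=True)
class ModelParameters:
    """Epidemiological and noise constants.

    Parameters
    ----------
    beta
        Transmission coefficient (1/time).
    b
        Common birth = death rate (1/time).  Birth and death rates of the
        infected and non-infected classes are assumed equal, so only one
        constant is stored; this keeps the total population constant.
    p
        Fraction of offspring of infected parents born susceptible,
        ``0 < p < 1``.  The infected fraction is ``q = 1 - p``.
    m
        Proportion of the susceptible class successfully vaccinated,
        ``0 < m < 1``.
    alpha1, alpha2
        Inhibition constants of the Crowley–Martin incidence (>= 0).
    gamma
        Recovery rate (1/time).
    omega
        Vaccine validity period / waning-immunity delay (time, >= 0).
    sigma
        White-noise intensity on the transmission coefficient (>= 0).
    """

    beta: float
    b: float
    p: float
    m: float
    alpha1: float = 0.0
    alpha2: float = 0.0
    gamma: float = 0.0
    omega: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not self.b > 0:
            raise ValueError(f"b must be > 0, got {self.b}")
        if not 0 < self.p < 1:
            raise ValueError(f"p must lie in (0, 1), got {self.p}")
        if not 0 < self.m < 1:
            raise ValueError(f"m must lie in (0, 1), got {self.m}")
        for name in ("alpha1", "alpha2", "gamma", "omega", "sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def q(self) -> float:
        """Fraction of offspring of infected parents born infected."""
        return 1.0 - self.p

    @property
    def waning_leak(self) -> float:
        """Net vaccination loss rate ``m * (1 - e^{-b omega})``.

        The fraction of vaccinated susceptibles that never returns: those
        dying before their immunity wanes.
        """
        return self.m * (1.0 - math.exp(-self.b * self.omega))

    def cm_denominator_scale(self) -> float:
        """The recurring factor ``b + alpha1*b + m*(1 - e^{-b omega})``."""
        return self.b + self.alpha1 * self.b + self.waning_leak


@dataclass(frozen=True)
class EpidemicState:
    """Population fractions (S, I, R) at time ``t``."""

    S: float
    I: float
    R: float
    t: float = 0.0

    def __post_init__(self) -> None:
        # tolerate roundoff from simplex arithmetic like 1 - S - I
        if self.S < -1e-12 or self.I < -1e-12 or self.R < -1e-12:
            raise ValueError(f"state components must be >= 0: {self}")

    @property
    def total(self) -> float:
        return self.S + self.I + self.R


@dataclass(frozen=True)
class EquilibriumSet:
    """Disease-free and (when it exists) endemic equilibria.

    The endemic equilibrium exists iff the bilinear reproduction number
    exceeds one; both triples sum to 1.
    """

    disease_free: tuple[float, float, float]
    endemic: Optional[tuple[float, float, float]] = None


@dataclass
class ThresholdReport:
    """All closed-form thresholds, bounds and the regime classification.

    ``lambda_a`` / ``lambda_b`` are the two almost-sure exponential decay
    bounds on ``ln I(t)/t`` — available when the large-noise condition (a)
    resp. the sub-threshold condition (b) holds.  ``lambda_I`` is the
    tighter (most negative) of the available bounds.  ``i_star`` is the
    persistence-in-the-mean lower bound, present when the stochastic
    threshold exceeds one.
    """

    r0_bilinear: float
    r0_cm: float
    r0_stochastic: float
    delta_cap: float
    cond_a: bool
    cond_b: bool
    lambda_a: Optional[float] = None
    lambda_b: Optional[float] = None
    lambda_I: Optional[float] = None
    i_star: Optional[float] = None
    regime: str = "undetermined"

    def to_dict(self) -> dict:
        """Flat JSON-ready mapping (``None`` for absent values)."""
        return {
            "r0_1": self.r0_bilinear,
            "r0_2": self.r0_cm,
            "r0_s": self.r0_stochastic,
            "delta_cap": self.delta_cap,
            "cond_a": self.cond_a,
            "cond_b": self.cond_b,
            "lambda_a": self.lambda_a,
            "lambda_b": self.lambda_b,
            "lambda_I": self.lambda_I,
            "i_star": self.i_star,
            "regime": self.regime,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def crowley_martin_denominator(s: float, i: float, params: ModelParameters) -> float:
    """Denominator ``1 + a1*s + a2*i + a1*a2*s*i`` of the incidence.

    Always >= 1 for nonnegative fractions; equals 1 in the bilinear limit
    ``alpha1 = alpha2 = 0``.
    """
    if s < 0 or i < 0:
        raise ValueError(f"fractions must be >= 0, got s={s}, i={i}")
    a1, a2 = params.alpha1, params.alpha2
    return 1.0 + a1 * s + a2 * i + a1 * a2 * s * i


def incidence_rate(s: float, i: float, params: ModelParameters) -> float:
    """Crowley–Martin incidence ``beta*s*i / (1 + a1*s + a2*i + a1*a2*s*i)``."""
    return params.beta * s * i / crowley_martin_denominator(s, i, params)


def delta_cap(params: ModelParameters) -> float:
    """Cap of the invariant region: ``b / (b + m(1 - e^{-b omega}))``.

    Trajectories started with ``S + I`` below this value never leave the
    region (deterministically; almost surely in the stochastic model).
    """
    return params.b / (params.b + params.waning_leak)


def r0_bilinear(params: ModelParameters) -> float:
    """Basic reproduction number of the bilinear-incidence model.

    ``beta*b / ((b + m(1 - e^{-b omega})) (p*b + gamma))`` — independent of
    the inhibition constants and the noise intensity.
    """
    return (
        params.beta
        * params.b
        / ((params.b + params.waning_leak) * (params.p * params.b + params.gamma))
    )


def r0_cm(params: ModelParameters) -> float:
    """Basic reproduction number under the Crowley–Martin incidence.

    ``beta*b / ((b + alpha1*b + m(1 - e^{-b omega})) (p*b + gamma))``;
    coincides with :func:`r0_bilinear` when ``alpha1 = 0`` and is never
    larger.
    """
    return (
        params.beta
        * params.b
        / (params.cm_denominator_scale() * (params.p * params.b + params.gamma))
    )


def r0_stochastic(params: ModelParameters) -> float:
    """Noise-corrected stochastic threshold.

    ``R0_2 * (1 - sigma^2 b / (2 beta (b + alpha1 b + m(1 - e^{-b omega}))))``.
    Below one (with the noise cap of condition (b)) the infection dies out
    almost surely; above one it persists in the mean.
    """
    correction = params.sigma**2 * params.b / (2.0 * params.beta * params.cm_denominator_scale())
    return r0_cm(params) * (1.0 - correction)


def equilibria(params: ModelParameters) -> EquilibriumSet:
    """Disease-free and endemic equilibria of the bilinear delayed model.

    The disease-free point is ``(S0, 0, R0)`` with
    ``S0 = b/(b + m(1-e^{-b omega}))``.  The endemic point exists iff
    ``r0_bilinear > 1``: ``S_e = (b p + gamma)/beta``,
    ``I_e = b/(b + gamma) (1 - 1/R0_1)`` and ``R_e`` closing the triple to
    sum 1 (closed form below); substituting it into the steady-state
    right-hand side cancels exactly.
    """
    leak = params.waning_leak
    denom = params.b + leak
    disease_free = (params.b / denom, 0.0, leak / denom)

    r01 = r0_bilinear(params)
    endemic = None
    if r01 > 1.0:
        beta, b, p, g = params.beta, params.b, params.p, params.gamma
        s_e = (b * p + g) / beta
        i_e = b / (b + g) * (1.0 - 1.0 / r01)
        r_e = (beta * g * r01 + beta * b - (b * p + g) * (b + g) * r01) / (
            beta * r01 * (b + g)
        )
        endemic = (s_e, i_e, r_e)
    return EquilibriumSet(disease_free=disease_free, endemic=endemic)


def extinction_conditions(
    params: ModelParameters,
) -> tuple[bool, bool, Optional[float], Optional[float]]:
    """Evaluate the two almost-sure extinction conditions.

    Returns ``(cond_a, cond_b, lambda_a, lambda_b)`` where

    * condition (a): ``sigma^2 > beta^2 / (2 (p b + gamma))`` — noise large
      enough to kill the outbreak regardless of the thresholds; then
      ``lambda_a = beta^2/(2 sigma^2) - (p b + gamma)``;
    * condition (b): ``r0_stochastic < 1`` together with the noise cap
      ``sigma^2 <= beta (b + alpha1 b + m(1-e^{-b omega})) / b``; then
      ``lambda_b = (r0_stochastic - 1) (p b + gamma)``.

    Each bound, when present, is strictly negative and dominates
    ``limsup ln I(t)/t`` almost surely.  The two conditions are not
    mutually exclusive; both bounds are returned when both hold.
    """
    removal = params.p * params.b + params.gamma
    sig2 = params.sigma**2

    cond_a = sig2 > params.beta**2 / (2.0 * removal)
    lambda_a = params.beta**2 / (2.0 * sig2) - removal if cond_a else None

    r0s = r0_stochastic(params)
    noise_cap = params.beta * params.cm_denominator_scale() / params.b
    cond_b = (r0s < 1.0) and (sig2 <= noise_cap)
    lambda_b = (r0s - 1.0) * removal if cond_b else None

    return cond_a, cond_b, lambda_a, lambda_b


def persistence_bound(params: ModelParameters) -> Optional[float]:
    """Lower bound ``I*`` on the long-run time average of I.

    Present only when ``r0_stochastic > 1``::

        I* = (p b + g)(R0_s - 1)(b + a1 b + L)(b + L)
             / ( beta [ (b + g)(b + L) + a2 b (b + L + a1 a2 b^2) ] )

    with ``L = m (1 - e^{-b omega})``.  In the noise-free bilinear limit
    (``alpha1 = alpha2 = sigma = 0``) it reduces exactly to the endemic
    equilibrium value ``I_e``.
    """
    r0s = r0_stochastic(params)
    if r0s <= 1.0:
        return None
    b, g = params.b, params.gamma
    leak = params.waning_leak
    scale = params.cm_denominator_scale()
    num = (params.p * b + g) * (r0s - 1.0) * scale * (b + leak)
    den = params.beta * (
        (b + g) * (b + leak)
        + params.alpha2 * b * (b + leak + params.alpha1 * params.alpha2 * b**2)
    )
    return num / den


def classify_regime(params: ModelParameters) -> ThresholdReport:
    """Aggregate every threshold and bound into a full report.

    Regime labels:

    * ``extinct_b`` — sub-threshold extinction (condition (b) holds);
    * ``extinct_a`` — large-noise extinction (condition (a) holds and (b)
      does not);
    * ``persistent`` — ``r0_stochastic > 1`` and neither condition holds;
    * ``undetermined`` — the theory makes no claim.

    When both extinction conditions hold, both decay bounds are reported
    and ``lambda_I`` is the tighter (most negative) one.
    """
    cond_a, cond_b, lambda_a, lambda_b = extinction_conditions(params)
    r0s = r0_stochastic(params)

    bounds = [x for x in (lambda_a, lambda_b) if x is not None]
    lambda_i = min(bounds) if bounds else None

    if cond_b:
        regime = "extinct_b"
    elif cond_a:
        regime = "extinct_a"
    elif r0s > 1.0:
        regime = "persistent"
    else:
        regime = "undetermined"

    return ThresholdReport(
        r0_bilinear=r0_bilinear(params),
        r0_cm=r0_cm(params),
        r0_stochastic=r0s,
        delta_cap=delta_cap(params),
        cond_a=cond_a,
        cond_b=cond_b,
        lambda_a=lambda_a,
        lambda_b=lambda_b,
        lambda_I=lambda_i,
        i_star=persistence_bound(params),
        regime=regime,
    )
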