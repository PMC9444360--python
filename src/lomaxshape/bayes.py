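"""Bayes point estimators of the Lomax shape parameter.

With the scale known, the likelihood depends on the data only through
T = sum ln(1 + x_i/scale), and every prior considered here (extended
Jeffreys, chi-square, inverted Levy, gamma) yields a Gamma posterior
theta | data ~ Gamma(shape=A, rate=B):

    prior                A            B
    extended Jeffreys    n - 2c + 1   T
    chi-square(k, d)     n + k/2      T + d/2
    inverted Levy(d)     n + 1/2      T + d/2
    gamma(k, d)          n + k        T + d

Each loss then gives a closed-form functional of (A, B):

    squared error (posterior mean)   A / B
    LINEX(a)                         (A/a) * ln(1 + a/B)
    composite LINEX(a)               (A/(2a)) * ln((B + a)/(B - a))

LINEX penalises over- and under-estimation asymmetrically; the composite
form symmetrises it by summing the losses at +a and -a.  Both collapse to
the posterior mean as a -> 0.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .model import SufficientStat

__all__ = [
    "PriorFamily",
    "PriorSpec",
    "GammaPosterior",
    "Loss",
    "LossSpec",
    "posterior",
    "estimate_self",
    "estimate_linex",
    "estimate_composite_linex",
    "bayes_estimate",
]


class PriorFamily(str, enum.Enum):
    EXTENDED_JEFFREYS = "extended_jeffreys"
    CHI_SQUARE = "chi_square"
    INVERTED_LEVY = "inverted_levy"
    GAMMA = "gamma"


@dataclass(frozen=True)
class PriorSpec:
    """A prior family with its hyperparameters.

    ``c`` is the extended-Jeffreys exponent (prior proportional to
    theta^(-2c)); ``k`` and ``d`` parameterise the conjugate families.
    Defaults match the study constants c=0.5, (k, d)=(0.6, 0.2).
    """

    family: PriorFamily
    c: float = 0.5
    k: float = 0.6
    d: float = 0.2

    def __post_init__(self) -> None:
        family = PriorFamily(self.family)
        object.__setattr__(self, "family", family)
        if family is PriorFamily.EXTENDED_JEFFREYS and not (self.c > 0):
            raise ValueError("extended Jeffreys prior requires c > 0")
        if family in (PriorFamily.CHI_SQUARE, PriorFamily.GAMMA):
            if not (self.k > 0 and self.d > 0):
                raise ValueError("chi-square/gamma priors require k > 0 and d > 0")
        if family is PriorFamily.INVERTED_LEVY and not (self.d > 0):
            raise ValueError("inverted Levy prior requires d > 0")


@dataclass(frozen=True)
class GammaPosterior:
    """Posterior Gamma(shape=A, rate=B); density proportional to theta^(A-1) e^(-B theta)."""

    shape_A: float
    rate_B: float

    def __post_init__(self) -> None:
        if not (self.shape_A > 0):
            raise ValueError(
                f"improper posterior: shape {self.shape_A} <= 0 "
                "(extended Jeffreys needs n > 2c - 1)"
            )
        if not (self.rate_B > 0):
            raise ValueError("posterior rate must be > 0 (degenerate sample, T = 0?)")


class Loss(str, enum.Enum):
    SELF = "self"
    LINEX = "linex"
    COMPOSITE_LINEX = "composite_linex"


@dataclass(frozen=True)
class LossSpec:
    loss: Loss
    a: float = 1.0

    def __post_init__(self) -> None:
        loss = Loss(self.loss)
        object.__setattr__(self, "loss", loss)
        if loss is Loss.LINEX and self.a == 0:
            raise ValueError("LINEX requires a != 0")
        if loss is Loss.COMPOSITE_LINEX and not (self.a > 0):
            raise ValueError("composite LINEX requires a > 0")


def posterior(prior: PriorSpec, stat: SufficientStat) -> GammaPosterior:
    """Map (prior, sufficient statistic) to the Gamma posterior (A, B)."""
    n, T = stat.n, stat.T
    if prior.family is PriorFamily.EXTENDED_JEFFREYS:
        return GammaPosterior(n - 2.0 * prior.c + 1.0, T)
    if prior.family is PriorFamily.CHI_SQUARE:
        return GammaPosterior(n + prior.k / 2.0, T + prior.d / 2.0)
    if prior.family is PriorFamily.INVERTED_LEVY:
        return GammaPosterior(n + 0.5, T + prior.d / 2.0)
    return GammaPosterior(n + prior.k, T + prior.d)


def estimate_self(post: GammaPosterior) -> float:
    """Posterior mean A / B (optimal under squared-error loss)."""
    return post.shape_A / post.rate_B


def estimate_linex(post: GammaPosterior, a: float) -> float:
    """LINEX rule -(1/a) ln E[e^(-a theta)] = (A/a) ln(1 + a/B).

    Needs a > -B for E[e^(-a theta)] to be finite.
    """
    if a == 0:
        raise ValueError("a must be nonzero; use estimate_self for the a -> 0 limit")
    if a <= -post.rate_B:
        raise ValueError(f"E[exp(-a*theta)] diverges for a = {a} <= -B = {-post.rate_B}")
    return (post.shape_A / a) * math.log1p(a / post.rate_B)


def estimate_composite_linex(post: GammaPosterior, a: float) -> float:
    """Composite-LINEX rule (1/2a) ln(E[e^(a theta)]/E[e^(-a theta)]) = (A/2a) ln((B+a)/(B-a)).

    Needs 0 < a < B for the moment generating function at +a to exist.
    """
    if not (a > 0):
        raise ValueError("composite LINEX requires a > 0")
    if a >= post.rate_B:
        raise ValueError(f"E[exp(a*theta)] diverges for a = {a} >= B = {post.rate_B}")
    # (1/2) ln((B+a)/(B-a)) = artanh(a/B), which stays accurate as a -> 0
    return (post.shape_A / a) * math.atanh(a / post.rate_B)


def bayes_estimate(prior: PriorSpec, loss: LossSpec, stat: SufficientStat) -> float:
    """Posterior + loss dispatch covering all prior-loss combinations."""
    post = posterior(prior, stat)
    if loss.loss is Loss.SELF:
        return estimate_self(post)
    if loss.loss is Loss.LINEX:
        return estimate_linex(post, loss.a)
    return estimate_composite_linex(post, loss.a)
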