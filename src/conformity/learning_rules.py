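"""Frequency-dependent social learning rules.

Two families of maps from a demonstrator frequency ``q`` to an adoption
probability ``p``:

* the classical three-demonstrator conformist bias
  ``p(q) = q + D*q*(1-q)*(2q-1)`` with bias strength ``D`` in [0, 1];
* the logistic (discrete-choice) family
  ``p(q) = q**beta / (q**beta + (1-q)**beta)``, whose single exponent
  ``beta`` spans hyper-conformity (beta > 1), unbiased copying
  (beta = 1), weak conformity (0 < beta < 1) and anti-conformity
  (beta <= 0), optionally mixed with a uniform error rate ``alpha`` so
  that even unanimous majorities are defected from with probability
  ``alpha/2``.

The logistic family has a random-utility micro-foundation: an agent who
picks the trait maximizing ``ln(q_j)`` plus i.i.d. Gumbel (Extreme Value
Type-I) noise with scale ``1/beta`` chooses trait ``j`` with probability
``q_j**beta / sum_k q_k**beta``.  :func:`sample_choice` draws from that
utility model directly, which makes it an independent Monte-Carlo oracle
for the closed forms as well as the decision sampler used by the
metapopulation simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit, logit

from .errors import DegenerateInputError, DomainError

__all__ = [
    "BoydRichersonRule",
    "LogisticRule",
    "RegimeLabel",
    "boyd_richerson_prob",
    "logistic_prob",
    "multi_logistic_probs",
    "sample_choice",
    "classify_regime",
    "validate_frequencies",
]

FREQ_SUM_TOL = 1e-9


@dataclass(frozen=True)
class BoydRichersonRule:
    """Three-demonstrator conformist bias with strength ``D`` in [0, 1]."""

    D: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.D <= 1.0) or not math.isfinite(self.D):
            raise DomainError(f"bias strength D must lie in [0, 1], got {self.D!r}")

    def prob(self, q):
        return boyd_richerson_prob(q, self)


@dataclass(frozen=True)
class LogisticRule:
    """Logistic learning rule with conformity strength ``beta`` (any real)
    and uniform error rate ``alpha`` in [0, 1] (default 0)."""

    beta: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.beta):
            raise DomainError(f"beta must be finite, got {self.beta!r}")
        if not (0.0 <= self.alpha <= 1.0) or not math.isfinite(self.alpha):
            raise DomainError(f"error rate alpha must lie in [0, 1], got {self.alpha!r}")

    def prob(self, q):
        return logistic_prob(q, self)

    def probs(self, freqs):
        return multi_logistic_probs(freqs, self)


@dataclass(frozen=True)
class RegimeLabel:
    """Qualitative learning regime implied by ``beta`` alone."""

    label: str
    note: Optional[str] = None


def _check_unit_interval(q, name: str) -> np.ndarray:
    arr = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0.0) or np.any(arr > 1.0):
        bad = arr[~(np.isfinite(arr) & (arr >= 0.0) & (arr <= 1.0))]
        raise DomainError(f"{name} must lie in [0, 1], got {bad.ravel()[:5]}")
    return arr


def validate_frequencies(freqs) -> np.ndarray:
    """Validate a vector of trait shares: length >= 2, entries in [0, 1],
    summing to 1 within ``1e-9``.  Returns the vector as a float array."""
    arr = _check_unit_interval(freqs, "frequencies")
    if arr.ndim != 1 or arr.size < 2:
        raise DomainError(f"need a 1-d vector of >= 2 trait frequencies, got shape {arr.shape}")
    total = float(arr.sum())
    if abs(total - 1.0) > FREQ_SUM_TOL:
        raise DomainError(f"frequencies must sum to 1 within {FREQ_SUM_TOL}, got {total!r}")
    return arr


def boyd_richerson_prob(q, rule: BoydRichersonRule | float):
    """Adoption probability ``q + D*q*(1-q)*(2q-1)``.

    ``D = 0`` is unbiased copying; ``D = 1`` equals the majority-of-three
    sampling model ``q**3 + 3*q**2*(1-q)``.  Accepts scalar or array ``q``.
    """
    if not isinstance(rule, BoydRichersonRule):
        rule = BoydRichersonRule(float(rule))
    arr = _check_unit_interval(q, "q")
    p = arr + rule.D * arr * (1.0 - arr) * (2.0 * arr - 1.0)
    # algebraically within [0,1] for D in [0,1]; clip float dust only
    p = np.clip(p, 0.0, 1.0)
    return p if np.ndim(q) else float(p)


def _logistic_core(arr: np.ndarray, beta: float) -> np.ndarray:
    """q**beta / (q**beta + (1-q)**beta) on the open interval, endpoints
    by continuity for beta > 0, error for beta <= 0 at an endpoint."""
    at_zero = arr == 0.0
    at_one = arr == 1.0
    if beta <= 0.0 and np.any(at_zero | at_one):
        raise DegenerateInputError(
            f"logistic rule with beta={beta} <= 0 is undefined at a unanimity "
            "endpoint (q = 0 or 1)"
        )
    p = np.empty_like(arr)
    interior = ~(at_zero | at_one)
    # logit form avoids overflow of q**beta at large |beta|
    p[interior] = expit(beta * logit(arr[interior]))
    p[at_zero] = 0.0
    p[at_one] = 1.0
    return p


def logistic_prob(q, rule: LogisticRule):
    """Probability of adopting the focal trait under the logistic rule.

    With ``alpha > 0`` the learner instead picks one of the two traits
    uniformly at random with probability ``alpha``, giving
    ``alpha/2 + (1 - alpha) * q**beta / (q**beta + (1-q)**beta)``.
    Endpoints for ``beta > 0`` resolve by continuity (p(0)=0, p(1)=1,
    then mixed with alpha); for ``beta <= 0`` they raise
    :class:`DegenerateInputError`.  Accepts scalar or array ``q``.
    """
    arr = _check_unit_interval(q, "q")
    p = _logistic_core(arr, rule.beta)
    if rule.alpha > 0.0:
        p = rule.alpha / 2.0 + (1.0 - rule.alpha) * p
    return p if np.ndim(q) else float(p)


def multi_logistic_probs(freqs, rule: LogisticRule) -> np.ndarray:
    """Adoption probabilities ``p_i = q_i**beta / sum_j q_j**beta`` over
    K >= 2 traits, mixed with a uniform error component ``alpha/K``.

    Zero shares require ``beta > 0`` (their choice weight is then 0); the
    output sums to 1 within 1e-12.
    """
    arr = validate_frequencies(freqs)
    zero = arr == 0.0
    if rule.beta <= 0.0 and np.any(zero):
        raise DegenerateInputError(
            f"multi-trait logistic rule with beta={rule.beta} <= 0 is undefined "
            "when a trait has zero share"
        )
    logw = np.full(arr.shape, -np.inf)
    logw[~zero] = rule.beta * np.log(arr[~zero])
    logw -= logw.max()  # stabilize before exponentiating
    w = np.exp(logw)
    p = w / w.sum()
    if rule.alpha > 0.0:
        p = rule.alpha / arr.size + (1.0 - rule.alpha) * p
    return p


def sample_choice(freqs, rule: LogisticRule, rng: np.random.Generator) -> int:
    """Draw one trait index from the random-utility model.

    The agent maximizes ``ln(q_j) + eps_j`` with i.i.d. Gumbel noise of
    scale ``1/beta``, equivalently ``beta*ln(q_j) + Gumbel(0, 1)``; with
    probability ``alpha`` it instead picks uniformly among the K traits.
    Choice probabilities equal :func:`multi_logistic_probs` exactly.
    Requires ``beta > 0``; a zero-share trait is never chosen by the
    utility branch.
    """
    arr = validate_frequencies(freqs)
    if rule.beta <= 0.0:
        raise DomainError(f"sample_choice requires beta > 0, got {rule.beta}")
    if rule.alpha > 0.0 and rng.random() < rule.alpha:
        return int(rng.integers(arr.size))
    with np.errstate(divide="ignore"):
        utilities = rule.beta * np.log(arr) + rng.gumbel(size=arr.size)
    return int(np.argmax(utilities))


def classify_regime(beta: float) -> RegimeLabel:
    """Map ``beta`` to its qualitative regime.

    beta > 1: hyper-conformity (disproportionate adoption of the
    majority variant); beta = 1: unbiased copying; 0 < beta < 1: weak
    conformity; beta <= 0: anti-conformity, with beta = 0 flagged as the
    uniform-random boundary where every trait is chosen with equal
    probability regardless of its frequency.
    """
    if not math.isfinite(beta):
        raise DomainError(f"beta must be finite, got {beta!r}")
    if beta > 1.0:
        return RegimeLabel("hyper-conformity")
    if beta == 1.0:
        return RegimeLabel("unbiased")
    if beta > 0.0:
        return RegimeLabel("weak-conformity")
    note = None
    if beta == 0.0:
        note = "boundary case: frequency-independent uniform choice (p = 1/K for every trait)"
    return RegimeLabel("anti-conformity", note=note)
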