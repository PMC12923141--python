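"""Core model: payoffs, selection gradient, feedbacks, vector field, Jacobian.

The model is a collective-risk social dilemma played in groups of ``N``
individuals sampled from an infinite well-mixed population.  Cooperators pay a
cost ``c`` into a common pool; if at least ``M`` group members cooperate the
group succeeds and everyone keeps their endowment ``b``, otherwise all members
lose the endowment with probability ``r`` (the collective risk).  Three
quantities coevolve:

* ``x`` — fraction of cooperators, driven by the replicator equation;
* ``r`` — collective risk, pushed up by defection and down by cooperation;
* ``c`` — cooperation cost, pushed up by defection and risk, down by
  cooperation, and confined to ``[beta, alpha]``.

The resulting dynamical system is

    eps1 * dx/dt = x (1-x) [ b r C(N-1, M-1) x^(M-1) (1-x)^(N-M) - c ]
    eps2 * dr/dt = r (1-r) [ mu1 (1-x) - mu2 x ]
           dc/dt = (alpha-c)(c-beta) [ th1 (1-x) - th2 x + th3 r - th4 (1-r) ]

on the invariant box [0,1] x [0,1] x [beta, alpha].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from math import comb
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "DomainError",
    "ModelParams",
    "State",
    "chi",
    "payoff_cooperator",
    "payoff_defector",
    "benefit",
    "benefit_derivative",
    "benefit_peak",
    "gradient_summation",
    "gradient_closed_form",
    "risk_feedback",
    "cost_feedback",
    "vector_field",
    "jacobian",
    "success_rate",
]


class DomainError(ValueError):
    """An argument fell outside the model's admissible domain."""


@dataclass(frozen=True)
class ModelParams:
    """All fixed constants of the game and both feedback layers.

    Parameters
    ----------
    N : int
        Group size (number of sampled participants), ``N >= 2``.
    M : int
        Cooperation threshold: the group succeeds when at least ``M`` of the
        ``N`` members cooperate, ``1 <= M <= N``.
    b : float
        Initial endowment of every participant (payoff units).
    alpha, beta : float
        Upper and lower bounds of the cooperation cost, ``alpha > beta > 0``.
    mu1, mu2 : float
        Risk-feedback coefficients: defectors raise risk at rate ``mu1``,
        cooperators lower it at rate ``mu2``.  Both strictly positive.
    theta1, theta2, theta3, theta4 : float
        Cost-feedback coefficients: defection (``theta1``) and risk
        (``theta3``) raise the cost; cooperation (``theta2``) and safety
        (``theta4``) lower it.  All strictly positive.
    eps1, eps2 : float
        Relative timescales of the strategy and risk updates.  The default
        ``eps1 = eps2 = 1`` recovers the plain coupled system.
    """

    N: int
    M: int
    b: float
    alpha: float
    beta: float
    mu1: float
    mu2: float
    theta1: float
    theta2: float
    theta3: float
    theta4: float
    eps1: float = 1.0
    eps2: float = 1.0

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 2:
            raise DomainError(f"N must be an integer >= 2, got {self.N}")
        if int(self.M) != self.M or not 1 <= self.M <= self.N:
            raise DomainError(f"M must satisfy 1 <= M <= N, got M={self.M}, N={self.N}")
        if self.b <= 0:
            raise DomainError(f"b must be positive, got {self.b}")
        if not self.beta > 0:
            raise DomainError(f"beta must be positive, got {self.beta}")
        if not self.alpha > self.beta:
            raise DomainError(
                f"alpha must exceed beta, got alpha={self.alpha}, beta={self.beta}"
            )
        for name in ("mu1", "mu2", "theta1", "theta2", "theta3", "theta4"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive, got {getattr(self, name)}")
        for name in ("eps1", "eps2"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive, got {getattr(self, name)}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class State:
    """A point (x, r, c) in the invariant box [0,1] x [0,1] x [beta, alpha]."""

    x: float
    r: float
    c: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.r, self.c], dtype=float)

    def validate(self, params: ModelParams, slack: float = 0.0) -> None:
        if not -slack <= self.x <= 1 + slack:
            raise DomainError(f"x out of [0, 1]: {self.x}")
        if not -slack <= self.r <= 1 + slack:
            raise DomainError(f"r out of [0, 1]: {self.r}")
        if not params.beta - slack <= self.c <= params.alpha + slack:
            raise DomainError(
                f"c out of [beta, alpha] = [{params.beta}, {params.alpha}]: {self.c}"
            )


def _as_state(state: "State | Sequence[float] | np.ndarray") -> tuple[float, float, float]:
    if isinstance(state, State):
        return state.x, state.r, state.c
    x, r, c = np.asarray(state, dtype=float)
    return float(x), float(r), float(c)


def chi(xi: float) -> int:
    """Heaviside-type step: 1 when xi >= 0, else 0 (threshold met at equality)."""
    return 1 if xi >= 0 else 0


def _check_group(n_c: int, params: ModelParams, r: float) -> None:
    if int(n_c) != n_c or not 0 <= n_c <= params.N:
        raise DomainError(f"cooperator count must be an integer in [0, N], got {n_c}")
    if not 0 <= r <= 1:
        raise DomainError(f"risk must lie in [0, 1], got {r}")


def payoff_cooperator(n_c: int, params: ModelParams, r: float, c: float) -> float:
    """Payoff of a cooperator in a group with ``n_c`` cooperators (focal included).

    The cooperator keeps the endowment ``b`` when the threshold is met
    (``n_c >= M``) and keeps it with probability ``1 - r`` otherwise; the cost
    ``c`` is paid unconditionally.
    """
    _check_group(n_c, params, r)
    met = chi(n_c - params.M)
    return params.b * met + (1.0 - r) * params.b * (1 - met) - c


def payoff_defector(n_c: int, params: ModelParams, r: float) -> float:
    """Payoff of a defector in a group containing ``n_c`` cooperators."""
    _check_group(n_c, params, r)
    met = chi(n_c - params.M)
    return params.b * met + (1.0 - r) * params.b * (1 - met)


def benefit(x: float, params: ModelParams) -> float:
    """Benefit term of the selection gradient.

    ``b * C(N-1, M-1) * x**(M-1) * (1-x)**(N-M)`` — the marginal expected
    gain a focal cooperator provides by being the pivotal M-th contributor
    among N-1 binomially sampled co-players, scaled by the endowment.  The
    convention ``0**0 = 1`` keeps M = 1 and M = N well defined at the
    boundary.
    """
    N, M = params.N, params.M
    return params.b * comb(N - 1, M - 1) * x ** (M - 1) * (1.0 - x) ** (N - M)


def benefit_derivative(x: float, params: ModelParams) -> float:
    """d/dx of :func:`benefit`; exponent-zero terms drop out exactly."""
    N, M = params.N, params.M
    coeff = params.b * comb(N - 1, M - 1)
    term = 0.0
    if M - 1 > 0:
        term += (M - 1) * x ** (M - 2) * (1.0 - x) ** (N - M)
    if N - M > 0:
        term -= (N - M) * x ** (M - 1) * (1.0 - x) ** (N - M - 1)
    return coeff * term


def benefit_peak(params: ModelParams) -> tuple[float, float]:
    """Argmax and maximum of the benefit term over x in [0, 1].

    The maximum sits at ``x_hat = (M-1)/(N-1)`` with value
    ``b * ((N-M)/(N-1))**(N-M) * ((M-1)/(N-1))**(M-1) * C(N-1, M-1)`` — the
    existence bound for the pair of edge equilibria.
    """
    N, M = params.N, params.M
    x_hat = (M - 1) / (N - 1)
    return x_hat, benefit(x_hat, params)


def gradient_summation(x: float, r: float, c: float, params: ModelParams) -> float:
    """Selection gradient f_C - f_D by exact binomial expectation.

    Averages the cooperator and defector payoffs over the number of
    cooperators among the N-1 co-players (the focal cooperator adds itself to
    its own group count).  Agrees with :func:`gradient_closed_form` to
    floating-point accuracy; kept as the independent summation route.
    """
    if not 0 <= x <= 1:
        raise DomainError(f"x must lie in [0, 1], got {x}")
    N = params.N
    f_c = 0.0
    f_d = 0.0
    for k in range(N):
        w = comb(N - 1, k) * x**k * (1.0 - x) ** (N - 1 - k)
        f_c += w * payoff_cooperator(k + 1, params, r, c)
        f_d += w * payoff_defector(k, params, r)
    return f_c - f_d


def gradient_closed_form(x: float, r: float, c: float, params: ModelParams) -> float:
    """Closed-form selection gradient ``b r C(N-1,M-1) x^(M-1) (1-x)^(N-M) - c``."""
    return benefit(x, params) * r - c


def risk_feedback(x: float, r: float, params: ModelParams) -> float:
    """Risk dynamics U1 = r (1-r) [mu1 (1-x) - mu2 x].

    Defectors push the risk toward 1, cooperators toward 0; the logistic
    prefactor pins the faces r = 0 and r = 1.
    """
    return r * (1.0 - r) * (params.mu1 * (1.0 - x) - params.mu2 * x)


def cost_feedback(x: float, r: float, c: float, params: ModelParams) -> float:
    """Cost dynamics U2 = (alpha-c)(c-beta)[th1(1-x) - th2 x + th3 r - th4(1-r)].

    Defection and risk inflate the cost, cooperation and safety deflate it;
    the quadratic prefactor pins the faces c = alpha and c = beta.
    """
    drive = (
        params.theta1 * (1.0 - x)
        - params.theta2 * x
        + params.theta3 * r
        - params.theta4 * (1.0 - r)
    )
    return (params.alpha - c) * (c - params.beta) * drive


FeedbackPair = tuple[
    Callable[[float, float, "ModelParams"], float],
    Callable[[float, float, float, "ModelParams"], float],
]


def vector_field(
    state: "State | Sequence[float]",
    params: ModelParams,
    feedbacks: FeedbackPair | None = None,
) -> np.ndarray:
    """Right-hand side (dx/dt, dr/dt, dc/dt) of the coupled system.

    ``feedbacks`` may supply an alternative ``(U1, U2)`` pair with the same
    signatures as :func:`risk_feedback` / :func:`cost_feedback`; the default
    pair gives the linear-feedback model analysed throughout this package.
    The timescale factors enter as ``dx/dt = .../eps1`` and ``dr/dt =
    .../eps2``; with the default eps values the plain system is recovered.
    """
    x, r, c = _as_state(state)
    u1, u2 = (risk_feedback, cost_feedback) if feedbacks is None else feedbacks
    dx = x * (1.0 - x) * gradient_closed_form(x, r, c, params) / params.eps1
    dr = u1(x, r, params) / params.eps2
    dc = u2(x, r, c, params)
    return np.array([dx, dr, dc])


def jacobian(state: "State | Sequence[float]", params: ModelParams) -> np.ndarray:
    """Analytic 3x3 Jacobian of :func:`vector_field` (default feedbacks).

    Valid on the closed box, including faces and corners; the model has no
    cost-to-risk coupling, so the (r, c) entry is identically zero.
    """
    x, r, c = _as_state(state)
    p = params
    g = benefit(x, p)
    dg = benefit_derivative(x, p)

    j = np.zeros((3, 3))
    # strategy row
    grad = g * r - c
    j[0, 0] = ((1.0 - 2.0 * x) * grad + x * (1.0 - x) * r * dg) / p.eps1
    j[0, 1] = x * (1.0 - x) * g / p.eps1
    j[0, 2] = -x * (1.0 - x) / p.eps1
    # risk row
    drive_r = p.mu1 * (1.0 - x) - p.mu2 * x
    j[1, 0] = -r * (1.0 - r) * (p.mu1 + p.mu2) / p.eps2
    j[1, 1] = (1.0 - 2.0 * r) * drive_r / p.eps2
    # cost row
    drive_c = (
        p.theta1 * (1.0 - x) - p.theta2 * x + p.theta3 * r - p.theta4 * (1.0 - r)
    )
    pref = (p.alpha - c) * (c - p.beta)
    j[2, 0] = -pref * (p.theta1 + p.theta2)
    j[2, 1] = pref * (p.theta3 + p.theta4)
    j[2, 2] = (p.alpha + p.beta - 2.0 * c) * drive_c
    return j


def success_rate(p: float, params: ModelParams) -> float:
    """Probability that a random group of N reaches the threshold M.

    With the population stabilised at cooperator frequency ``p`` this is the
    binomial upper tail ``P(X >= M)``, ``X ~ Binomial(N, p)``, computed by
    the explicit complementary sum so that dyadic-rational inputs evaluate
    exactly.
    """
    if not 0 <= p <= 1:
        raise DomainError(f"cooperator frequency must lie in [0, 1], got {p}")
    N, M = params.N, params.M
    tail = 0.0
    for k in range(M):
        tail += comb(N, k) * p**k * (1.0 - p) ** (N - k)
    return 1.0 - tail
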