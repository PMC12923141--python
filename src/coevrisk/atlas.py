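"""Equilibrium atlas: enumeration and stability classification of fixed points.

The coupled system has at most sixteen fixed points, organised by how many
coordinates sit on the boundary of the box [0,1] x [0,1] x [beta, alpha]:

* eight **corners** ``{0,1} x {0,1} x {beta, alpha}`` — always present; of
  these only the tragedy-of-the-commons state ``(0, 1, alpha)`` is stable;
* two pairs of **edge** points ``(x, 1, c0)`` with ``c0`` pinned at ``alpha``
  or ``beta``, where ``x`` solves ``benefit(x) = c0``; they exist when the
  unimodal benefit term peaks above ``c0`` and come as a lower root (always
  a saddle) and an upper root (stable under a threshold condition);
* up to three **surface** points with one coordinate pinned: on ``c = beta``
  and ``c = alpha`` at the risk-balance frequency ``x* = mu1/(mu1+mu2)``, and
  on ``r = 1`` at the cost-balance frequency ``Rx = (th1+th3)/(th1+th2)``;
* one **interior** point, always unstable when it exists.

Stability is classified twice: by closed-form criteria (sign conditions on
the auxiliary quantities T1, T5, B1, B5 and on threshold ratios) and by the
eigenvalues of the analytic Jacobian.  The two verdicts agree whenever the
fixed point is hyperbolic, which is the headline consistency check of the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model import ModelParams, benefit, benefit_peak, jacobian, vector_field

__all__ = [
    "Equilibrium",
    "StabilityReport",
    "corner_equilibria",
    "edge_equilibria",
    "surface_equilibria",
    "interior_equilibrium",
    "enumerate_equilibria",
    "table1_verdict",
    "eigen_verdict",
    "classify",
    "stability_atlas",
    "stable_equilibria",
    "atlas_report",
]

#: default half-width of the marginal band around the imaginary axis
EIG_TOL = 1e-9

KINDS = (
    "corner",
    "edge_alpha",
    "edge_beta",
    "surface_beta",
    "surface_ridge",
    "surface_alpha",
    "interior",
)


@dataclass(frozen=True)
class Equilibrium:
    """A labelled fixed point of the coupled system.

    ``exists`` is False for records whose existence condition fails under the
    given parameters (coordinates are then a best-effort placeholder and must
    not be interpreted).  ``branch`` distinguishes the paired edge roots
    (``lower`` < ``upper``); ``degenerate`` flags a double root, which is
    reported as non-existent.
    """

    kind: str
    x: float
    r: float
    c: float
    exists: bool
    branch: str | None = None
    degenerate: bool = False
    cost_tag: str | None = None  # 'alpha'/'beta' for corners (pinned cost level)

    @property
    def label(self) -> str:
        if self.kind == "corner":
            return f"corner({self.x:g},{self.r:g},{self.cost_tag})"
        if self.kind in ("edge_alpha", "edge_beta"):
            return f"{self.kind}_{self.branch}"
        return self.kind

    def coords(self) -> np.ndarray:
        return np.array([self.x, self.r, self.c])


@dataclass
class StabilityReport:
    """Eigenvalue and closed-form stability verdicts for one equilibrium."""

    eigenvalues: np.ndarray
    verdict_eigen: str  # stable | unstable | marginal
    verdict_table1: str  # stable | unstable | not_applicable
    auxiliaries: dict = field(default_factory=dict)


def corner_equilibria(params: ModelParams) -> list[Equilibrium]:
    """The eight vertices of the state box; all are fixed points."""
    out = []
    for x in (0.0, 1.0):
        for r in (0.0, 1.0):
            for c, tag in ((params.alpha, "alpha"), (params.beta, "beta")):
                out.append(Equilibrium("corner", x, r, c, exists=True, cost_tag=tag))
    return out


def _resolve_level(level, params: ModelParams) -> tuple[float, str]:
    if level in ("alpha", params.alpha):
        return params.alpha, "edge_alpha"
    if level in ("beta", params.beta):
        return params.beta, "edge_beta"
    raise ValueError(f"cost level must be 'alpha' or 'beta' (or their values), got {level!r}")


def edge_equilibria(params: ModelParams, level="alpha", xtol: float = 1e-14) -> list[Equilibrium]:
    """The two roots of ``benefit(x) = c0`` on the edge ``r = 1, c = c0``.

    The benefit term is unimodal with peak at ``x_hat = (M-1)/(N-1)``, so the
    lower root is bracketed by ``[0, x_hat]`` and the upper by ``[x_hat, 1]``
    and both are found by Brent's method.  When the peak does not exceed
    ``c0`` (or equals it, a degenerate double root) the pair is reported as
    non-existent.  For M = 1 or M = N the benefit term is monotone and only
    the single bracketed root is returned as existing.
    """
    c0, kind = _resolve_level(level, params)
    x_hat, peak = benefit_peak(params)

    def f(x: float) -> float:
        return benefit(x, params) - c0

    degenerate = abs(peak - c0) <= 1e-12
    roots: dict[str, float | None] = {"lower": None, "upper": None}
    if peak > c0 and not degenerate:
        if x_hat > 0.0 and f(0.0) < 0.0:
            roots["lower"] = brentq(f, 0.0, x_hat, xtol=xtol)
        if x_hat < 1.0 and f(1.0) < 0.0:
            roots["upper"] = brentq(f, x_hat, 1.0, xtol=xtol)
    out = []
    for branch in ("lower", "upper"):
        xr = roots[branch]
        exists = xr is not None
        out.append(
            Equilibrium(
                kind,
                xr if exists else float("nan"),
                1.0,
                c0,
                exists=exists,
                branch=branch,
                degenerate=degenerate,
            )
        )
    return out


def surface_equilibria(params: ModelParams) -> list[Equilibrium]:
    """Fixed points with exactly one coordinate pinned to a face.

    * ``surface_beta`` — ``(x*, Br, beta)`` with ``x* = mu1/(mu1+mu2)`` and
      ``Br = beta / benefit(x*)``; exists iff ``0 < Br < 1``.
    * ``surface_alpha`` — ``(x*, Tr, alpha)`` with ``Tr = alpha/benefit(x*)``;
      exists iff ``0 < Tr < 1``.
    * ``surface_ridge`` — ``(Rx, 1, Rc)`` on the maximal-risk face, with
      ``Rx = (th1+th3)/(th1+th2)`` and ``Rc = benefit(Rx)``; exists iff
      ``th3 < th2`` (so that ``Rx < 1``) and ``beta < Rc < alpha``.
    """
    p = params
    x_star = p.mu1 / (p.mu1 + p.mu2)
    g_star = benefit(x_star, p)
    out = []

    br = p.beta / g_star if g_star > 0 else float("inf")
    out.append(Equilibrium("surface_beta", x_star, br, p.beta, exists=0.0 < br < 1.0))

    tr = p.alpha / g_star if g_star > 0 else float("inf")
    out.append(Equilibrium("surface_alpha", x_star, tr, p.alpha, exists=0.0 < tr < 1.0))

    rx = (p.theta1 + p.theta3) / (p.theta1 + p.theta2)
    rc = benefit(rx, p) if rx <= 1.0 else float("nan")
    ridge_exists = p.theta3 < p.theta2 and p.beta < rc < p.alpha
    out.append(Equilibrium("surface_ridge", rx, 1.0, rc, exists=ridge_exists))
    return out


def interior_equilibrium(params: ModelParams) -> Equilibrium:
    """The unique candidate interior fixed point ``(x*, r*, c*)``.

    ``r* = (th2 mu1 - th1 mu2 + th4 (mu1+mu2)) / ((th3+th4)(mu1+mu2))`` and
    ``c* = benefit(x*) r*``; exists iff ``0 < r* < 1`` and
    ``beta < c* < alpha``.  Always unstable when it exists.
    """
    p = params
    x_star = p.mu1 / (p.mu1 + p.mu2)
    r_star = (p.theta2 * p.mu1 - p.theta1 * p.mu2 + p.theta4 * (p.mu1 + p.mu2)) / (
        (p.theta3 + p.theta4) * (p.mu1 + p.mu2)
    )
    c_star = benefit(x_star, p) * r_star
    exists = 0.0 < r_star < 1.0 and p.beta < c_star < p.alpha
    return Equilibrium("interior", x_star, r_star, c_star, exists=exists)


def enumerate_equilibria(params: ModelParams) -> list[Equilibrium]:
    """All sixteen candidate fixed points, existence-flagged."""
    out = corner_equilibria(params)
    out += edge_equilibria(params, "alpha")
    out += edge_equilibria(params, "beta")
    out += surface_equilibria(params)
    out.append(interior_equilibrium(params))
    return out


def _threshold_ratios(params: ModelParams) -> tuple[float, float]:
    mu_ratio = params.mu1 / (params.mu1 + params.mu2)
    theta_ratio = (params.theta1 + params.theta3) / (params.theta1 + params.theta2)
    return mu_ratio, theta_ratio


def _surface_auxiliaries(params: ModelParams) -> dict:
    """T1, T5, B1, B5 as printed in the stability table.

    T1 and B1 are written in the expanded grouping
    ``alpha (M - N x* - x*) + alpha (2 x* - 1)``, which simplifies to
    ``alpha (M - 1 - (N-1) x*)``; the expanded form is kept verbatim and the
    simplification is asserted in the test suite.
    """
    p = params
    x_s = p.mu1 / (p.mu1 + p.mu2)
    g = benefit(x_s, p)
    tr = p.alpha / g if g > 0 else float("inf")
    br = p.beta / g if g > 0 else float("inf")

    def drive(r: float) -> float:
        return (
            p.theta1 * (1.0 - x_s)
            - p.theta2 * x_s
            + p.theta3 * r
            - p.theta4 * (1.0 - r)
        )

    return {
        "x_star": x_s,
        "Tr": tr,
        "Br": br,
        "T1": p.alpha * (p.M - p.N * x_s - x_s) + p.alpha * (2.0 * x_s - 1.0),
        "T5": (p.beta - p.alpha) * drive(tr),
        "B1": p.beta * (p.M - p.N * x_s - x_s) + p.beta * (2.0 * x_s - 1.0),
        "B5": (p.alpha - p.beta) * drive(br),
    }


def table1_verdict(eq: Equilibrium, params: ModelParams) -> tuple[str, dict]:
    """Closed-form stability verdict and the auxiliary quantities it used.

    Criteria: the corner ``(0, 1, alpha)`` is stable and the other corners
    unstable; the lower edge roots, the maximal-risk surface point and the
    interior point are unstable; the upper edge root at ``c = alpha`` is
    stable iff ``x2 < min(mu1/(mu1+mu2), (th1+th3)/(th1+th2))``; the upper
    edge root at ``c = beta`` is stable iff it lies strictly between those two
    ratios (cost ratio below, risk ratio above); the cost-face surface points
    are stable iff ``T1 < 0 and T5 < 0`` (``c = alpha``) respectively
    ``B1 < 0 and B5 < 0`` (``c = beta``).
    """
    if not eq.exists:
        return "not_applicable", {}
    mu_ratio, theta_ratio = _threshold_ratios(params)
    aux: dict = {"mu_ratio": mu_ratio, "theta_ratio": theta_ratio}

    if eq.kind == "corner":
        stable = eq.x == 0.0 and eq.r == 1.0 and eq.c == params.alpha
        return ("stable" if stable else "unstable"), aux
    if eq.kind in ("edge_alpha", "edge_beta"):
        if eq.branch == "lower":
            return "unstable", aux
        if eq.kind == "edge_alpha":
            stable = eq.x < min(mu_ratio, theta_ratio)
        else:
            stable = theta_ratio < eq.x < mu_ratio
        return ("stable" if stable else "unstable"), aux
    if eq.kind == "surface_ridge" or eq.kind == "interior":
        return "unstable", aux
    saux = _surface_auxiliaries(params)
    aux.update(saux)
    if eq.kind == "surface_alpha":
        stable = saux["T1"] < 0.0 and saux["T5"] < 0.0
    elif eq.kind == "surface_beta":
        stable = saux["B1"] < 0.0 and saux["B5"] < 0.0
    else:  # pragma: no cover - exhaustive over KINDS
        raise ValueError(f"unknown equilibrium kind {eq.kind!r}")
    return ("stable" if stable else "unstable"), aux


def eigen_verdict(
    eq: Equilibrium, params: ModelParams, tol: float = EIG_TOL
) -> tuple[np.ndarray, str]:
    """Eigenvalues of the full 3D Jacobian at the fixed point and the verdict.

    Boundary equilibria are linearised in all three directions (including
    those leaving the box), matching the closed-form table.  ``marginal`` is
    returned when the leading real part lies within ``tol`` of zero.
    """
    if not eq.exists:
        return np.full(3, np.nan, dtype=complex), "not_applicable"
    eigvals = np.linalg.eigvals(jacobian(eq.coords(), params))
    re = eigvals.real
    if np.all(re < -tol):
        verdict = "stable"
    elif np.any(re > tol):
        verdict = "unstable"
    else:
        verdict = "marginal"
    return eigvals, verdict


def classify(eq: Equilibrium, params: ModelParams, tol: float = EIG_TOL) -> StabilityReport:
    """Both stability verdicts plus the auxiliary closed-form quantities."""
    v_t1, aux = table1_verdict(eq, params)
    eigvals, v_eig = eigen_verdict(eq, params, tol)
    return StabilityReport(eigvals, v_eig, v_t1, aux)


def stability_atlas(
    params: ModelParams, tol: float = EIG_TOL
) -> list[tuple[Equilibrium, StabilityReport]]:
    """Every candidate equilibrium with its stability report."""
    return [(eq, classify(eq, params, tol)) for eq in enumerate_equilibria(params)]


def stable_equilibria(params: ModelParams, tol: float = EIG_TOL) -> list[Equilibrium]:
    """Existing equilibria whose eigenvalue verdict is 'stable'."""
    return [
        eq
        for eq, rep in stability_atlas(params, tol)
        if eq.exists and rep.verdict_eigen == "stable"
    ]


def atlas_report(params: ModelParams, tol: float = EIG_TOL) -> list[dict]:
    """JSON-serialisable atlas: one record per candidate equilibrium."""
    out = []
    for eq, rep in stability_atlas(params, tol):
        rec = {
            "kind": eq.kind,
            "branch": eq.branch,
            "x": None if np.isnan(eq.x) else eq.x,
            "r": eq.r,
            "c": None if np.isnan(eq.c) else eq.c,
            "exists": eq.exists,
            "degenerate": eq.degenerate,
            "eigenvalues": [
                [float(v.real), float(v.imag)] if eq.exists else [None, None]
                for v in rep.eigenvalues
            ],
            "verdict_table1": rep.verdict_table1,
            "verdict_eigen": rep.verdict_eigen,
            "auxiliaries": {k: float(v) for k, v in rep.auxiliaries.items()},
        }
        if eq.exists:
            rec["residual"] = float(np.linalg.norm(vector_field(eq.coords(), params)))
        out.append(rec)
    return out
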