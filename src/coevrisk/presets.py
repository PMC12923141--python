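"""Named parameter sets covering the model's representative regimes.

All presets share the baseline game (N = 8, M = 5, b = 2, cost bounds
beta = 0.1, alpha = 0.3, mu2 = 0.3, theta1 = 0.5, theta4 = 0.6) and differ
in the feedback coefficients mu1, theta2, theta3, which select the
multistability regime.  The two ``sweep_*`` sets are the fixed backgrounds
for the threshold-M sweeps at the high-cost (c = alpha) and low-cost
(c = beta) edge attractors.
"""

from __future__ import annotations

from .model import ModelParams

__all__ = ["PRESETS", "get_preset"]

_BASE = dict(
    N=8, M=5, b=2.0, alpha=0.3, beta=0.1, mu2=0.3, theta1=0.5, theta4=0.6
)

PRESETS: dict[str, ModelParams] = {
    # only the tragedy corner (0, 1, alpha) is stable
    "monostable": ModelParams(**_BASE, mu1=0.25, theta2=0.5, theta3=0.6),
    # corner + upper edge root at maximal cost
    "bistable_edge_alpha": ModelParams(**_BASE, mu1=2.5, theta2=0.7, theta3=0.6),
    # corner + upper edge root at minimal cost
    "bistable_edge_beta": ModelParams(**_BASE, mu1=2.5, theta2=0.7, theta3=0.15),
    # corner + both upper edge roots
    "tristable_two_edges": ModelParams(**_BASE, mu1=2.5, theta2=0.5, theta3=0.3),
    # corner + surface point on the c = beta face
    "bistable_surface_beta": ModelParams(**_BASE, mu1=0.7, theta2=0.5, theta3=0.2),
    # corner + c = beta surface point + high-cost edge root
    "tristable_surface_edge": ModelParams(**_BASE, mu1=1.4, theta2=0.5, theta3=0.8),
    # corner + both cost-face surface points
    "tristable_two_surfaces": ModelParams(**_BASE, mu1=0.9, theta2=0.5, theta3=0.8),
    # threshold sweep backgrounds (M is varied by the sweep itself)
    "sweep_edge_alpha": ModelParams(**_BASE, mu1=2.5, theta2=0.7, theta3=0.6),
    "sweep_edge_beta": ModelParams(**_BASE, mu1=2.5, theta2=2.0, theta3=0.15),
}


def get_preset(name: str) -> ModelParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
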