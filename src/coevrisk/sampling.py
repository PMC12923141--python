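"""Random valid parameter draws for property tests and robustness studies."""

from __future__ import annotations

import numpy as np

from .model import ModelParams

__all__ = ["sample_params"]


def sample_params(seed: int, n: int = 1) -> list[ModelParams]:
    """Draw ``n`` valid parameter sets, deterministic under ``seed``.

    Ranges reflect the magnitudes used across the model's regimes: feedback
    coefficients mu, theta in [0.05, 3], endowment b in [1, 5], cost bounds
    0 < beta < alpha <= 1, group size N in 4..12 with interior threshold
    2 <= M <= N-1.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        N = int(rng.integers(4, 13))
        M = int(rng.integers(2, N))
        beta, alpha = np.sort(rng.uniform(0.02, 1.0, size=2))
        if alpha - beta < 1e-3:
            alpha = beta + 1e-3
        coeffs = rng.uniform(0.05, 3.0, size=6)
        out.append(
            ModelParams(
                N=N,
                M=M,
                b=float(rng.uniform(1.0, 5.0)),
                alpha=float(alpha),
                beta=float(beta),
                mu1=float(coeffs[0]),
                mu2=float(coeffs[1]),
                theta1=float(coeffs[2]),
                theta2=float(coeffs[3]),
                theta3=float(coeffs[4]),
                theta4=float(coeffs[5]),
            )
        )
    return out
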