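"""Combine per-dataset p-values into one summarized p-value P_A.

Four methods over p_1..p_k:

* minP               P_A = min(p_i)                      (anti-conservative;
                     reported as-is, no Sidak adjustment)
* Fisher             P_A = upper tail of chi2 with 2k df at -2 * sum(ln p_i)
* Stouffer           P_A = 1 - Phi(sum(Z_i) / sqrt(k)),  Z_i = Phi^-1(1 - p_i)
* weighted Stouffer  P_A = 1 - Phi(sum(w_i Z_i) / sqrt(sum(w_i^2)))
                     with w_i = 4 / (1/n_i_case + 1/n_i_control), i.e. four
                     times the harmonic-mean-based effective sample size.

The weight enters the numerator unsquared, matching the sqrt(sum w_i^2)
denominator; ``sqrt_weights=True`` opts into the common sqrt(N_eff)
convention instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

METHODS = ("minp", "fisher", "stouffer", "weighted_stouffer")

#: p-values this close to 1 are clamped so Phi^-1 stays finite
_P_CEIL = 1 - 1e-12


@dataclass
class CombinedResult:
    p_values: np.ndarray
    method: str
    p_combined: float
    z_values: np.ndarray | None = None
    weights: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.p_values.size


def stouffer_weights(counts) -> np.ndarray:
    """w_i = 4 / (1/n_case + 1/n_control) per dataset."""
    counts = [(int(a), int(b)) for a, b in counts]
    if any(a <= 0 or b <= 0 for a, b in counts):
        raise ValueError("case/control counts must be positive")
    return np.array([4.0 / (1.0 / a + 1.0 / b) for a, b in counts])


def combine(p, method: str = "fisher", counts=None,
            sqrt_weights: bool = False) -> CombinedResult:
    """Summarize k per-dataset p-values into P_A.

    ``counts`` — an iterable of (n_case, n_control) pairs — is required for
    (and only used by) the weighted Stouffer method.
    """
    method = method.replace("-", "_").lower()
    if method not in METHODS:
        raise ValueError(f"unknown combination method {method!r}; use {METHODS}")
    p = np.asarray(list(p), dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")

    z_values = weights = None
    if method == "minp":
        p_combined = float(p.min())
    elif method == "fisher":
        stat = -2.0 * np.log(p).sum()
        p_combined = float(stats.chi2.sf(stat, df=2 * p.size))
    else:
        z_values = stats.norm.ppf(1 - np.minimum(p, _P_CEIL))
        if method == "stouffer":
            p_combined = float(stats.norm.sf(z_values.sum() / np.sqrt(p.size)))
        else:
            if counts is None:
                raise ValueError("weighted_stouffer requires per-dataset (n_case, n_control) counts")
            weights = stouffer_weights(counts)
            if weights.size != p.size:
                raise ValueError("one (n_case, n_control) pair required per p-value")
            if sqrt_weights:
                weights = np.sqrt(weights)
            num = (weights * z_values).sum()
            p_combined = float(stats.norm.sf(num / np.sqrt((weights ** 2).sum())))
    return CombinedResult(p_values=p, method=method, p_combined=p_combined,
                          z_values=z_values, weights=weights)
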