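"""Conversions between probe intensities, beta-values and M-values.

The two standard summaries of Infinium methylation measurements are

* the beta-value  ``M / (M + U + alpha)``  in ``[0, 1)`` — the methylated
  fraction of the signal, regularised by a count offset ``alpha`` (default
  100) so that low-intensity probes do not explode, and
* the M-value  ``log2((M + alpha) / (U + alpha))`` — the log-ratio of the
  methylated and unmethylated channel intensities, with its own offset
  (default 1).  M-values are approximately homoscedastic across the
  methylation range, which is why the normalization in this package and the
  downstream statistics operate on the M scale.

Because almost all probes have intensities well above the offsets, the two
scales are related by the logit-like pair (offsets ignored)

    M = log2(beta / (1 - beta)),      beta = 2**M / (2**M + 1)

which this module implements with an explicit clamp so that beta in {0, 1}
maps to a finite M and the pair stays an exact inverse on the clamped
domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Offsets",
    "DEFAULT_BETA_OFFSET",
    "DEFAULT_M_OFFSET",
    "DEFAULT_BETA_CLAMP_EPS",
    "beta_from_intensities",
    "m_from_intensities",
    "beta_to_m",
    "m_to_beta",
]

DEFAULT_BETA_OFFSET = 100.0
DEFAULT_M_OFFSET = 1.0
DEFAULT_BETA_CLAMP_EPS = 1e-6


@dataclass(frozen=True)
class Offsets:
    """Count offsets and the beta clamp used by the scale conversions."""

    alpha_beta: float = DEFAULT_BETA_OFFSET
    alpha_m: float = DEFAULT_M_OFFSET
    beta_clamp_eps: float = DEFAULT_BETA_CLAMP_EPS

    def __post_init__(self) -> None:
        if self.alpha_beta < 0:
            raise ValueError(f"alpha_beta must be >= 0, got {self.alpha_beta}")
        if self.alpha_m < 0:
            raise ValueError(f"alpha_m must be >= 0, got {self.alpha_m}")
        if not 0 < self.beta_clamp_eps < 0.5:
            raise ValueError(
                f"beta_clamp_eps must lie in (0, 0.5), got {self.beta_clamp_eps}"
            )


def _asarray(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def beta_from_intensities(meth, unmeth, alpha_beta: float = DEFAULT_BETA_OFFSET):
    """beta = meth / (meth + unmeth + alpha_beta).

    ``alpha_beta`` regularises low-intensity probes; with the default of 100
    the result lies in ``[0, 1)``.
    """
    meth = _asarray(meth)
    unmeth = _asarray(unmeth)
    if np.any(meth < 0) or np.any(unmeth < 0):
        raise ValueError("intensities must be non-negative")
    if alpha_beta < 0:
        raise ValueError("alpha_beta must be >= 0")
    denom = meth + unmeth + alpha_beta
    if np.any(denom == 0):
        raise ValueError("meth + unmeth + alpha_beta must be positive")
    out = meth / denom
    return out if out.ndim else float(out)


def m_from_intensities(meth, unmeth, alpha_m: float = DEFAULT_M_OFFSET):
    """M = log2((meth + alpha_m) / (unmeth + alpha_m))."""
    meth = _asarray(meth)
    unmeth = _asarray(unmeth)
    if np.any(meth < 0) or np.any(unmeth < 0):
        raise ValueError("intensities must be non-negative")
    if alpha_m < 0:
        raise ValueError("alpha_m must be >= 0")
    num = meth + alpha_m
    den = unmeth + alpha_m
    if np.any(num == 0) or np.any(den == 0):
        raise ValueError(
            "zero channel intensity with alpha_m = 0 leaves the M-value undefined"
        )
    out = np.log2(num / den)
    return out if out.ndim else float(out)


def beta_to_m(beta, eps: float = DEFAULT_BETA_CLAMP_EPS):
    """logit2 transform: M = log2(beta / (1 - beta)) after clamping.

    beta is clamped into ``[eps, 1 - eps]`` first so the boundary values map
    to finite M; values outside ``[0, 1]`` are rejected.
    """
    beta = _asarray(beta)
    if not 0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    finite = np.isfinite(beta)
    if np.any(finite & ((beta < 0) | (beta > 1))):
        raise ValueError("beta values must lie in [0, 1]")
    clamped = np.clip(beta, eps, 1.0 - eps)
    out = np.log2(clamped / (1.0 - clamped))
    out = np.where(finite, out, np.nan)
    return out if out.ndim else float(out)


def m_to_beta(m):
    """Inverse logit2: beta = 2**M / (2**M + 1), strictly in (0, 1).

    NaN propagates (missing cells); infinite M is rejected.
    """
    m = _asarray(m)
    if np.any(np.isinf(m)):
        raise ValueError("M-values must be finite")
    # expit formulation avoids overflow of 2**m for large |m|
    out = 1.0 / (1.0 + np.exp2(-m))
    return out if out.ndim else float(out)
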