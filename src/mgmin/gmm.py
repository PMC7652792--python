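"""EM fitting of one-dimensional Gaussian mixtures to per-sample M-values.

The M-values of a single 450K array are modelled as a finite Gaussian
mixture whose components correspond to methylation states: hypomethylated
(U, lowest mean), hemimethylated (H, around zero) and hypermethylated (F,
highest mean).  Each probe type (I and II) on each sample gets its own fit.

The defaults are deliberate: EM starts from means (-4, 0, 4), unit
standard deviations and uniform weights — the natural locations of the
three states on the M scale — and the fit is insensitive to small
perturbations of that start.  The number of type I components is escalated
from 3 to 4 when the fitted type I hypermethylated component sits too far
left relative to the type II one (``mu_I^F - sigma_I^F < mu_II^F -
sigma_II^F``); the 4-component refit adds a far-right start so the
highest-mean type I component can move past the type II one, which keeps
the downstream quantile mapping from creating a spurious peak among
hypermethylated type II probes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "GmmFit",
    "EmConfig",
    "InsufficientDataError",
    "DegenerateDataError",
    "UnsupportedKError",
    "fit_gmm",
    "select_K_type1",
    "relabel_states",
    "default_init",
]

#: minimum number of observations per mixture component required to fit
MIN_VALUES_PER_COMPONENT = 10


class InsufficientDataError(ValueError):
    """Fewer finite values than the fit requires (10 per component)."""


class DegenerateDataError(ValueError):
    """All input values identical; a mixture fit is meaningless."""


class UnsupportedKError(ValueError):
    """State relabelling is defined only for K in {3, 4}."""


def default_init(K: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Default EM starting values (means, sds, weights) for K components.

    K=3 starts at the canonical state locations (-4, 0, 4); K=4 adds a
    far-right component, (-4, 0, 3, 6), so the refit triggered by the
    K-selection rule can place a type I hypermethylated component to the
    right of the type II one.  Other K get evenly spaced means in [-4, 4].
    """
    if K == 3:
        means = np.array([-4.0, 0.0, 4.0])
    elif K == 4:
        means = np.array([-4.0, 0.0, 3.0, 6.0])
    elif K == 1:
        means = np.array([0.0])
    else:
        means = np.linspace(-4.0, 4.0, K)
    return means, np.ones(K), np.full(K, 1.0 / K)


@dataclass(frozen=True)
class EmConfig:
    """Tuning knobs for the EM fit.

    tol is the relative log-likelihood change declaring convergence;
    sigma_floor keeps components from collapsing onto near-duplicate
    values.  init_* override the defaults from :func:`default_init` and
    must match K when given.  seed is kept for jitter diagnostics only —
    the fit itself is deterministic given its initialization.
    """

    init_means: tuple[float, ...] | None = None
    init_sds: tuple[float, ...] | None = None
    init_weights: tuple[float, ...] | None = None
    tol: float = 1e-8
    max_iter: int = 500
    sigma_floor: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.sigma_floor <= 0:
            raise ValueError("sigma_floor must be positive")

    def initialization(self, K: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        means, sds, weights = default_init(K)
        if self.init_means is not None:
            means = np.asarray(self.init_means, dtype=float)
        if self.init_sds is not None:
            sds = np.asarray(self.init_sds, dtype=float)
        if self.init_weights is not None:
            weights = np.asarray(self.init_weights, dtype=float)
            weights = weights / weights.sum()
        if not (len(means) == len(sds) == len(weights) == K):
            raise ValueError("initialization vectors must have length K")
        return means, sds, weights


@dataclass
class GmmFit:
    """A fitted K-component univariate Gaussian mixture.

    Components are stored sorted by ascending mean, so for the three-state
    model index 0 is the hypomethylated (U) component, the last index the
    hypermethylated (F) component.
    """

    K: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik_trace: np.ndarray = field(repr=False)
    converged: bool
    n: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.loglik_trace = np.asarray(self.loglik_trace, dtype=float)
        if not (len(self.weights) == len(self.means) == len(self.sds) == self.K):
            raise ValueError("parameter vectors must have length K")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("components must be sorted by ascending mean")
        if np.any(self.sds <= 0):
            raise ValueError("component sds must be positive")

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        """Posterior component probabilities, shape (len(x), K)."""
        x = np.asarray(x, dtype=float)
        logp = (
            np.log(self.weights)[None, :]
            + norm.logpdf(x[:, None], self.means[None, :], self.sds[None, :])
        )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loglik": self.loglik,
            "n_iter": len(self.loglik_trace),
            "converged": self.converged,
            "n": self.n,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _log_mixture_density(x, weights, means, sds):
    comp = np.log(weights)[None, :] + norm.logpdf(
        x[:, None], means[None, :], sds[None, :]
    )
    m = comp.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(comp - m).sum(axis=1, keepdims=True)))[:, 0]


def fit_gmm(values, K: int = 3, config: EmConfig | None = None) -> GmmFit:
    """Fit a K-component Gaussian mixture to M-values by EM.

    Parameters
    ----------
    values
        Finite M-values of one probe type on one sample.
    K
        Number of components (methylation states).
    config
        EM settings; ``None`` uses the defaults of :class:`EmConfig`.

    Returns
    -------
    GmmFit with components sorted by ascending mean, the per-iteration
    log-likelihood trace, and a convergence flag (``False`` means the
    iteration cap was reached).
    """
    if config is None:
        config = EmConfig()
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite; drop missing cells before fitting")
    n = x.size
    if n < MIN_VALUES_PER_COMPONENT * K:
        raise InsufficientDataError(
            f"need at least {MIN_VALUES_PER_COMPONENT * K} values for K={K}, got {n}"
        )
    if np.ptp(x) == 0:
        raise DegenerateDataError("all values identical; cannot fit a mixture")

    means, sds, weights = (a.copy() for a in config.initialization(K))
    sds = np.maximum(sds, config.sigma_floor)

    trace: list[float] = []
    converged = False
    floored = False
    for _ in range(config.max_iter):
        # E step
        log_comp = np.log(weights)[None, :] + norm.logpdf(
            x[:, None], means[None, :], sds[None, :]
        )
        m = log_comp.max(axis=1, keepdims=True)
        log_total = m + np.log(np.exp(log_comp - m).sum(axis=1, keepdims=True))
        ll = float(log_total.sum())
        resp = np.exp(log_comp - log_total)

        if trace and abs(ll - trace[-1]) <= config.tol * abs(trace[-1]):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)

        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(var)
        if np.any(sds < config.sigma_floor):
            floored = True
            sds = np.maximum(sds, config.sigma_floor)

    if floored:
        warnings.warn(
            "a component standard deviation collapsed to the floor "
            f"({config.sigma_floor}); the fit may be degenerate",
            RuntimeWarning,
            stacklevel=2,
        )

    order = np.argsort(means, kind="stable")
    return GmmFit(
        K=K,
        weights=weights[order],
        means=means[order],
        sds=sds[order],
        loglik_trace=np.array(trace),
        converged=converged,
        n=n,
    )


def _check_three_component(fit: GmmFit, name: str) -> None:
    if fit.K != 3:
        raise ValueError(f"{name} must be a 3-component fit, got K={fit.K}")
    if np.any(np.diff(fit.means) < 0):
        raise ValueError(f"{name} components are not sorted by mean")


def select_K_type1(fit_I: GmmFit, fit_II: GmmFit) -> int:
    """Decide whether the type I fit needs a fourth component.

    Returns 4 exactly when ``mu_I^F - sigma_I^F < mu_II^F - sigma_II^F``
    (strict), where F is the highest-mean component of each 3-component
    fit; otherwise 3.  The escalation guarantees the type I
    hypermethylated component used as the quantile-mapping target lies to
    the right of the type II one, preventing an artefactual peak among
    normalized hypermethylated type II probes.
    """
    _check_three_component(fit_I, "fit_I")
    _check_three_component(fit_II, "fit_II")
    edge_I = fit_I.means[-1] - fit_I.sds[-1]
    edge_II = fit_II.means[-1] - fit_II.sds[-1]
    return 4 if edge_I < edge_II else 3


def relabel_states(fit: GmmFit) -> dict[int, str]:
    """Map sorted component indices to methylation states U/H/F.

    K=3: ascending means are U, H, F.  K=4: the lowest mean is U, the
    highest is F, and both middle components are treated as
    hemimethylated.
    """
    if fit.K == 3:
        return {0: "U", 1: "H", 2: "F"}
    if fit.K == 4:
        return {0: "U", 1: "H", 2: "H", 3: "F"}
    raise UnsupportedKError(f"state relabelling requires K in {{3, 4}}, got {fit.K}")
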