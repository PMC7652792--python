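"""The MGMIN normalization: map type II M-values onto the type I scale.

Per sample, the procedure is:

1. Fit 3-component Gaussian mixtures to the type I and type II M-values
   separately (:mod:`mgmin.gmm`).  If the fitted type I hypermethylated
   component sits left of the type II one (``mu_I^F - sigma_I^F <
   mu_II^F - sigma_II^F``) the type I model is refit with 4 components.
2. Assign every type II probe to a state U/H/F by maximum posterior
   probability, and split the U and F states at their component means
   into left (L) and right (R) halves.
3. Quantile-map the outer halves through the fitted Gaussians: a probe in
   U_IIL at value x has lower-tail probability p = Phi((x - mu_II^U) /
   sigma_II^U) under its own component and is sent to the M-value with
   the same probability under the type I U component,
   q = Phi^{-1}(p; mu_I^U, sigma_I^U).  F_IIR is mapped likewise with the
   F parameters.  For Gaussian source and target this composition is the
   affine map  q = mu_dst + sigma_dst * (x - mu_src) / sigma_src.
4. Merge the remaining probes, G = U_IIR + H_II + F_IIL, and apply a
   conformal (shift + dilation) map  x -> minG' + df * (x - minG)  whose
   endpoints are chosen to conserve the observed gaps between G and the
   quantile-mapped flanks (Delta_UG below minG, Delta_GF above maxG),
   with dilation factor df = (maxG' - minG') / (maxG - minG).  This keeps
   the normalized type II values continuous across the three pieces.

Type I values are never touched.  When the input matrix is on the beta
scale it is logit-transformed to M on entry and back-transformed on exit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gmm import EmConfig, GmmFit, InsufficientDataError, DegenerateDataError, \
    MIN_VALUES_PER_COMPONENT, fit_gmm, relabel_states, select_K_type1
from .io import MethylMatrix
from .values import DEFAULT_BETA_CLAMP_EPS, beta_to_m, m_to_beta

__all__ = [
    "StatePartition",
    "ConformalParams",
    "SampleProvenance",
    "NormalizationResult",
    "EmptyPartitionError",
    "assign_states",
    "quantile_map",
    "conformal_transform",
    "normalize_sample",
    "normalize_matrix",
]

#: probability clamp applied before inverting the Gaussian CDF, so that
#: extreme outliers cannot map to infinite quantiles
P_CLAMP = 1e-15

_STATES = ("U", "H", "F")


class EmptyPartitionError(ValueError):
    """One of the sets U_IIL, F_IIR or G is empty for a sample."""


@dataclass
class StatePartition:
    """Per-probe state (U/H/F) and side (L/R) labels for one sample.

    ``component`` holds the argmax posterior component index; ``state``
    the mapped methylation state; ``side`` is "L" when the value lies
    strictly below the representative mean of its state (lowest-mean
    component for U, highest-mean for F) and "R" otherwise.
    ``n_noncontiguous`` counts values whose argmax component differs from
    what a simple nearest-boundary rule would give — a diagnostic for
    non-contiguous posterior regions under unequal component SDs.
    """

    component: np.ndarray
    state: np.ndarray
    side: np.ndarray
    n_noncontiguous: int = 0

    def mask(self, state: str, side: str | None = None) -> np.ndarray:
        m = self.state == state
        if side is not None:
            m = m & (self.side == side)
        return m

    def counts(self) -> dict[str, int]:
        out = {}
        for s in _STATES:
            for sd in ("L", "R"):
                out[f"{s}{sd}"] = int(np.sum(self.mask(s, sd)))
        return out


@dataclass
class ConformalParams:
    """Endpoints and dilation factor of the conformal map for one sample.

    All quantities are M-values.  ``d_ug = minG - maxU`` and ``d_gf =
    minF - maxG`` are the gaps between the middle set G and the outer
    halves before normalization; the normalized endpoints are chosen so
    those gaps are conserved against the quantile-mapped flanks:
    ``minG_new = maxU_new + d_ug``, ``maxG_new = minF_new - d_gf``.
    """

    min_g: float
    max_g: float
    max_u: float
    min_f: float
    max_u_new: float
    min_f_new: float

    @property
    def delta_g(self) -> float:
        return self.max_g - self.min_g

    @property
    def d_ug(self) -> float:
        return self.min_g - self.max_u

    @property
    def d_gf(self) -> float:
        return self.min_f - self.max_g

    @property
    def min_g_new(self) -> float:
        return self.max_u_new + self.d_ug

    @property
    def max_g_new(self) -> float:
        return self.min_f_new - self.d_gf

    @property
    def delta_g_new(self) -> float:
        return self.max_g_new - self.min_g_new

    @property
    def df(self) -> float:
        """Dilation factor delta_g_new / delta_g."""
        if self.delta_g == 0:
            return float("nan")
        return self.delta_g_new / self.delta_g

    def to_dict(self) -> dict:
        return {
            "minG": self.min_g,
            "maxG": self.max_g,
            "delta_G": self.delta_g,
            "maxU": self.max_u,
            "minF": self.min_f,
            "delta_UG": self.d_ug,
            "delta_GF": self.d_gf,
            "maxU_new": self.max_u_new,
            "minF_new": self.min_f_new,
            "minG_new": self.min_g_new,
            "maxG_new": self.max_g_new,
            "delta_G_new": self.delta_g_new,
            "df": self.df,
        }


@dataclass
class SampleProvenance:
    """Everything needed to audit one sample's normalization."""

    fit_I: GmmFit
    fit_II: GmmFit
    fit_I3: GmmFit | None  # the initial 3-component type I fit when K_I=4
    k_type1: int
    k_rule: str  # "auto" or "forced"
    partition: StatePartition
    conformal: ConformalParams
    failed: bool = False
    failure_reason: str | None = None

    def to_dict(self) -> dict:
        if self.failed:
            return {"failed": True, "reason": self.failure_reason}
        return {
            "failed": False,
            "K_I": self.k_type1,
            "K_rule": self.k_rule,
            "fit_typeI": self.fit_I.to_dict(),
            "fit_typeII": self.fit_II.to_dict(),
            "fit_typeI_K3": None if self.fit_I3 is None else self.fit_I3.to_dict(),
            "partition_counts": self.partition.counts(),
            "n_noncontiguous": self.partition.n_noncontiguous,
            "conformal": self.conformal.to_dict(),
        }


@dataclass
class NormalizationResult:
    """Normalized matrix plus per-sample provenance.

    Type I rows are identical to the input; type II rows carry the
    corrected values.  ``provenance`` maps sample ID to
    :class:`SampleProvenance`; samples that could not be fitted are
    flagged there and passed through unnormalized.
    """

    matrix: MethylMatrix
    provenance: dict[str, SampleProvenance] = field(default_factory=dict)

    def provenance_dict(self) -> dict:
        return {s: p.to_dict() for s, p in self.provenance.items()}


def assign_states(values, fit: GmmFit, state_map: dict[int, str] | None = None) -> StatePartition:
    """Assign each value to a methylation state by maximum posterior.

    The winning component maximises ``pi_k * N(x | mu_k, sigma_k^2)``;
    ties break to the lower-mean component.  The side label splits each
    state at its representative mean: for U the lowest-mean component's
    mean, for F the highest-mean component's mean (values exactly at the
    mean go right).
    """
    if state_map is None:
        state_map = relabel_states(fit)
    x = np.asarray(values, dtype=float)
    logp = np.log(fit.weights)[None, :] + norm.logpdf(
        x[:, None], fit.means[None, :], fit.sds[None, :]
    )
    comp = np.argmax(logp, axis=1)  # argmax takes the first (lower-mean) on ties
    state = np.array([state_map[k] for k in range(fit.K)])[comp]

    h_means = [fit.means[k] for k in range(fit.K) if state_map[k] == "H"]
    rep_mean = {"U": fit.means[0], "H": float(np.mean(h_means)),
                "F": fit.means[-1]}
    thresh = np.array([rep_mean[s] for s in state])
    side = np.where(x < thresh, "L", "R")

    # diagnostic: posterior regions can be non-contiguous when SDs differ;
    # count order inversions of the assigned component along sorted values
    order = np.argsort(x, kind="stable")
    n_noncontig = int(np.sum(np.diff(comp[order]) < 0))
    return StatePartition(component=comp, state=state, side=side,
                          n_noncontiguous=n_noncontig)


def quantile_map(values, src_mu: float, src_sd: float,
                 dst_mu: float, dst_sd: float) -> np.ndarray:
    """Gaussian-to-Gaussian quantile mapping.

    Sends x to the value with the same cumulative probability under the
    target component: ``q = Phi^{-1}(Phi((x - src_mu)/src_sd); dst_mu,
    dst_sd)``.  The tail probability is clamped at 1e-15 before
    inversion; the upper tail is computed through the survival function
    so the composition stays accurate far from the mean.
    """
    if src_sd <= 0 or dst_sd <= 0:
        raise ValueError("component standard deviations must be positive")
    x = np.asarray(values, dtype=float)
    z = (x - src_mu) / src_sd
    out = np.empty_like(z)
    lower = z <= 0
    p = np.clip(norm.cdf(z[lower]), P_CLAMP, 1 - P_CLAMP)
    out[lower] = norm.ppf(p)
    sf = np.clip(norm.sf(z[~lower]), P_CLAMP, 1 - P_CLAMP)
    out[~lower] = norm.isf(sf)
    result = dst_mu + dst_sd * out
    return result if result.ndim else float(result)


def conformal_transform(g_values, params: ConformalParams) -> np.ndarray:
    """Shift + dilation of the middle set G: x -> minG' + df * (x - minG)."""
    x = np.asarray(g_values, dtype=float)
    if params.delta_g == 0:
        warnings.warn(
            "set G spans a single point; mapping it to the midpoint of the "
            "normalized range",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.full_like(x, 0.5 * (params.min_g_new + params.max_g_new))
    return params.min_g_new + params.df * (x - params.min_g)


def _fit_sample(m_typeI: np.ndarray, m_typeII: np.ndarray, config: EmConfig,
                k_type1: str | int = "auto"):
    """Fit both mixtures, applying the automatic K_I escalation rule."""
    fit_I3 = fit_gmm(m_typeI, K=3, config=config)
    fit_II = fit_gmm(m_typeII, K=3, config=config)
    if k_type1 == "auto":
        k_I = select_K_type1(fit_I3, fit_II)
        rule = "auto"
    else:
        k_I = int(k_type1)
        if k_I not in (3, 4):
            raise ValueError("k_type1 must be 'auto', 3 or 4")
        rule = "forced"
    if k_I == 4:
        fit_I = fit_gmm(m_typeI, K=4, config=config)
        kept3 = fit_I3
    else:
        fit_I = fit_I3
        kept3 = None
    return fit_I, fit_II, kept3, k_I, rule


def normalize_sample(m_typeI, m_typeII, config: EmConfig | None = None,
                     k_type1: str | int = "auto") -> tuple[np.ndarray, SampleProvenance]:
    """Normalize one sample's type II M-values onto the type I scale.

    Parameters
    ----------
    m_typeI, m_typeII
        Finite M-values of the two probe designs for a single array.
    config
        EM settings; defaults to :class:`EmConfig()`.
    k_type1
        "auto" applies the escalation rule; 3 or 4 force the component
        count (diagnostic use).

    Returns
    -------
    (normalized type II M-values in input order, SampleProvenance).
    Type I values are not returned: they pass through unchanged.
    """
    if config is None:
        config = EmConfig()
    m_typeI = np.asarray(m_typeI, dtype=float).ravel()
    m_typeII = np.asarray(m_typeII, dtype=float).ravel()
    if m_typeI.size == 0 or m_typeII.size == 0:
        raise ValueError("both probe-type value lists must be non-empty")

    fit_I, fit_II, fit_I3, k_I, rule = _fit_sample(m_typeI, m_typeII, config, k_type1)
    part = assign_states(m_typeII, fit_II)

    mask_ul = part.mask("U", "L")
    mask_fr = part.mask("F", "R")
    mask_g = ~(mask_ul | mask_fr)
    for name, mask in (("U_IIL", mask_ul), ("F_IIR", mask_fr), ("G", mask_g)):
        if not mask.any():
            raise EmptyPartitionError(f"partition set {name} is empty for this sample")

    # type I U/F parameters: lowest- and highest-mean components
    mu_I_U, sd_I_U = fit_I.means[0], fit_I.sds[0]
    mu_I_F, sd_I_F = fit_I.means[-1], fit_I.sds[-1]
    mu_II_U, sd_II_U = fit_II.means[0], fit_II.sds[0]
    mu_II_F, sd_II_F = fit_II.means[-1], fit_II.sds[-1]

    q_u = quantile_map(m_typeII[mask_ul], mu_II_U, sd_II_U, mu_I_U, sd_I_U)
    q_f = quantile_map(m_typeII[mask_fr], mu_II_F, sd_II_F, mu_I_F, sd_I_F)

    g = m_typeII[mask_g]
    params = ConformalParams(
        min_g=float(g.min()),
        max_g=float(g.max()),
        max_u=float(m_typeII[mask_ul].max()),
        min_f=float(m_typeII[mask_fr].min()),
        max_u_new=float(q_u.max()),
        min_f_new=float(q_f.min()),
    )
    g_new = conformal_transform(g, params)

    out = np.empty_like(m_typeII)
    out[mask_ul] = q_u
    out[mask_fr] = q_f
    out[mask_g] = g_new
    prov = SampleProvenance(fit_I=fit_I, fit_II=fit_II, fit_I3=fit_I3,
                            k_type1=k_I, k_rule=rule, partition=part,
                            conformal=params)
    return out, prov


def normalize_matrix(matrix: MethylMatrix, config: EmConfig | None = None,
                     k_type1: str | int = "auto",
                     beta_clamp_eps: float = DEFAULT_BETA_CLAMP_EPS) -> NormalizationResult:
    """Apply the per-sample normalization to every column of a matrix.

    Columns are independent.  Beta input is converted to M on entry and
    back on exit, so the output scale matches the input scale.  Missing
    cells are excluded from fitting and stay missing.  A sample with too
    few non-missing probes of either design is passed through
    unnormalized and flagged in the provenance.
    """
    if config is None:
        config = EmConfig()
    mask_I = matrix.type_mask("I")
    mask_II = matrix.type_mask("II")
    if not mask_I.any() or not mask_II.any():
        raise ValueError("matrix must contain both type I and type II probes")

    vals = matrix.values.to_numpy(dtype=float, copy=True)
    if matrix.scale == "beta":
        mvals = np.asarray(beta_to_m(vals, eps=beta_clamp_eps))
    else:
        mvals = vals.copy()

    out = mvals.copy()
    provenance: dict[str, SampleProvenance] = {}
    min_needed = MIN_VALUES_PER_COMPONENT * 3
    for j, sample in enumerate(matrix.sample_ids):
        col = mvals[:, j]
        obs_I = mask_I & np.isfinite(col)
        obs_II = mask_II & np.isfinite(col)
        try:
            if obs_I.sum() < min_needed or obs_II.sum() < min_needed:
                raise InsufficientDataError(
                    f"sample {sample}: {int(obs_I.sum())} type I and "
                    f"{int(obs_II.sum())} type II non-missing probes; "
                    f"need {min_needed} of each"
                )
            norm_II, prov = normalize_sample(col[obs_I], col[obs_II], config,
                                             k_type1=k_type1)
            out[obs_II, j] = norm_II
            provenance[str(sample)] = prov
        except (InsufficientDataError, DegenerateDataError, EmptyPartitionError) as exc:
            warnings.warn(f"sample {sample} left unnormalized: {exc}",
                          RuntimeWarning, stacklevel=2)
            provenance[str(sample)] = SampleProvenance(
                fit_I=None, fit_II=None, fit_I3=None, k_type1=0, k_rule="none",
                partition=None, conformal=None, failed=True,
                failure_reason=str(exc))

    if matrix.scale == "beta":
        finite = np.isfinite(out)
        res = np.full_like(out, np.nan)
        res[finite] = np.asarray(m_to_beta(out[finite]))
        # type I columns must round-trip bit-identically on the beta scale
        res[mask_I, :] = vals[mask_I, :]
        for sample, prov in provenance.items():
            if prov.failed:
                j = matrix.sample_ids.get_loc(sample)
                res[:, j] = vals[:, j]
        out_df = pd.DataFrame(res, index=matrix.probe_ids, columns=matrix.sample_ids)
        scale = "beta"
    else:
        out_df = pd.DataFrame(out, index=matrix.probe_ids, columns=matrix.sample_ids)
        scale = "m"

    flags = {s: p.failure_reason for s, p in provenance.items() if p.failed}
    normalized = MethylMatrix(values=out_df, probe_type=matrix.probe_type.copy(),
                              scale=scale, sample_flags=flags)
    return NormalizationResult(matrix=normalized, provenance=provenance)
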