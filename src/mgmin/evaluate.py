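"""Evaluation metrics for normalization quality.

Covers the three axes on which a design-bias correction is judged:

* technical variation — per-probe standard deviation across replicate
  arrays, and the mean absolute beta difference between replicate pairs
  over type II probes;
* distributional concordance — the two-sample Kolmogorov-Smirnov
  statistic between type I and (normalized) type II M-values, and
  max/mean/RMSE deviation summaries against a gold-standard reference
  such as bisulfite pyrosequencing;
* biological signal — differential methylation calling between two
  phenotype groups with a moderated t-statistic (empirical-Bayes
  variance shrinkage across probes, Benjamini-Hochberg FDR), the
  resulting DMP counts, and the positive predictive value nTP/nDMP when
  training-set DMPs are validated on an independent test set.

Sample quality control follows the detection-p convention: a probe is
"bad" in a sample when its detection p-value exceeds tau_p, and a sample
is dropped when its bad-probe fraction exceeds tau_r.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import MethylMatrix
from .values import beta_to_m, m_to_beta

__all__ = [
    "QcParams",
    "DmpResult",
    "probe_sd",
    "mean_abs_diff",
    "distribution_distance",
    "deviation_summary",
    "moderated_t",
    "detect_dmps",
    "count_true_positives",
    "ppv",
    "qc_filter_samples",
]


@dataclass(frozen=True)
class QcParams:
    """Detection-p threshold for bad probes and per-sample bad fraction cap."""

    tau_p: float
    tau_r: float

    def __post_init__(self) -> None:
        if not 0 < self.tau_p < 1:
            raise ValueError("tau_p must lie in (0, 1)")
        if not 0 < self.tau_r <= 0.3:
            raise ValueError("tau_r must lie in (0, 0.3]")


# ---------------------------------------------------------------------------
# technical variation


def probe_sd(matrix: MethylMatrix, replicate_group) -> pd.Series:
    """Per-probe sample SD across the named replicate columns (NA-aware)."""
    replicate_group = list(replicate_group)
    if len(replicate_group) < 2:
        raise ValueError("need at least two replicate samples")
    missing = [s for s in replicate_group if s not in matrix.sample_ids]
    if missing:
        raise ValueError(f"samples not in matrix: {', '.join(map(str, missing))}")
    return matrix.values[replicate_group].std(axis=1, ddof=1)


def mean_abs_diff(matrix: MethylMatrix, sample_a: str, sample_b: str,
                  probe_type: str = "II") -> float:
    """Mean |beta_a - beta_b| over probes of one design type (NA-aware).

    The difference is always taken on the beta scale; an M-scale matrix is
    converted first.
    """
    for s in (sample_a, sample_b):
        if s not in matrix.sample_ids:
            raise ValueError(f"sample {s!r} not in matrix")
    mask = matrix.type_mask(probe_type)
    a = matrix.values[sample_a].to_numpy(dtype=float)[mask]
    b = matrix.values[sample_b].to_numpy(dtype=float)[mask]
    if matrix.scale == "m":
        keep = np.isfinite(a) & np.isfinite(b)
        a = np.where(keep, a, np.nan)
        b = np.where(keep, b, np.nan)
        with np.errstate(invalid="ignore"):
            a = np.asarray(m_to_beta(np.nan_to_num(a)))
            b = np.asarray(m_to_beta(np.nan_to_num(b)))
        a[~keep] = np.nan
        b[~keep] = np.nan
    return float(np.nanmean(np.abs(a - b)))


# ---------------------------------------------------------------------------
# distributional concordance


def distribution_distance(values_a, values_b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic in [0, 1]."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def deviation_summary(values, reference) -> tuple[float, float, float]:
    """(max, mean, rmse) of elementwise absolute deviations |v - r|."""
    v = np.asarray(values, dtype=float)
    r = np.asarray(reference, dtype=float)
    if v.shape != r.shape:
        raise ValueError(f"length mismatch: {v.shape} vs {r.shape}")
    if v.size == 0:
        raise ValueError("need at least one value")
    d = np.abs(v - r)
    return float(d.max()), float(d.mean()), float(np.sqrt(np.mean(d ** 2)))


# ---------------------------------------------------------------------------
# differential methylation


@dataclass
class DmpResult:
    """Per-probe moderated-t results and the DMP set at an FDR threshold.

    ``table`` is indexed by probe ID with columns ``stat``, ``p``, ``q``,
    ``is_dmp``; probes with undefined statistics (constant values) carry
    NaN and are never DMPs.  ``d0`` and ``s0_sq`` are the fitted prior
    degrees of freedom and prior variance of the shrinkage.
    """

    table: pd.DataFrame
    fdr: float
    d0: float
    s0_sq: float
    scale: str

    @property
    def n_dmp(self) -> int:
        return int(self.table["is_dmp"].sum())

    @property
    def dmp_ids(self) -> pd.Index:
        return self.table.index[self.table["is_dmp"]]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return float("inf")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled F prior to the observed probe variances.

    Fits ``s2 ~ s0_sq * F(df, d0)`` through the moments of ``log(s2)``,
    returning (d0, s0_sq); d0 = inf means complete shrinkage to s0_sq.
    """
    ok = np.isfinite(s2) & (s2 > 0)
    s2 = s2[ok]
    df = df[ok]
    if s2.size < 2:
        return float("inf"), float(np.median(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = float("inf")
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def moderated_t(values: np.ndarray, labels: np.ndarray):
    """Two-group moderated t-statistics with empirical-Bayes shrinkage.

    Per probe, the pooled within-group variance is shrunk toward a prior
    fitted across probes, ``s2_post = (d0 * s0_sq + df * s2) / (d0 + df)``,
    and the t-statistic uses ``df + d0`` total degrees of freedom.

    Returns (stat, p, df_total, d0, s0_sq) arrays/floats; probes constant
    across all samples get NaN.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    g0 = labels == 0
    g1 = labels == 1
    if g0.sum() < 2 or g1.sum() < 2:
        raise ValueError("each group needs at least two samples")

    def _group(vals, mask):
        sub = vals[:, mask]
        finite = np.isfinite(sub)
        n = finite.sum(axis=1)
        total = np.where(finite, sub, 0.0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            mean = total / n
        ss = np.where(finite, (np.where(finite, sub, 0.0) - mean[:, None]) ** 2,
                      0.0).sum(axis=1)
        return n, mean, ss

    with np.errstate(invalid="ignore"):
        n0, m0, ss0 = _group(values, g0)
        n1, m1, ss1 = _group(values, g1)
    df = (n0 + n1 - 2).astype(float)
    usable = (n0 >= 2) & (n1 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(usable & (df > 0), (ss0 + ss1) / np.maximum(df, 1), np.nan)

    constant = usable & (s2 == 0) & (m0 == m1)
    fit_mask = usable & np.isfinite(s2) & (s2 > 0)
    d0, s0_sq = _fit_f_dist(s2[fit_mask], df[fit_mask])

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_post * (1.0 / n0 + 1.0 / n1))
        stat = (m1 - m0) / se
    p = 2.0 * stats.t.sf(np.abs(stat), np.where(np.isfinite(df_total), df_total,
                                                1e12))
    bad = ~usable | constant | ~np.isfinite(stat)
    stat = np.where(bad, np.nan, stat)
    p = np.where(bad, np.nan, p)
    return stat, p, df_total, d0, s0_sq


def detect_dmps(matrix: MethylMatrix, labels, fdr: float = 0.35,
                use_beta: bool = False) -> DmpResult:
    """Call differentially methylated probes between two groups.

    Testing runs on M-values (the homoscedastic scale) unless
    ``use_beta=True``; a beta matrix is converted as needed.  q-values
    are Benjamini-Hochberg; the DMP set is ``{q < fdr}``.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size != matrix.n_samples:
        raise ValueError(
            f"{labels.size} labels for {matrix.n_samples} samples")
    vals = matrix.values.to_numpy(dtype=float)
    scale = "beta" if use_beta else "m"
    if matrix.scale == "beta" and not use_beta:
        vals = np.asarray(beta_to_m(vals))
    elif matrix.scale == "m" and use_beta:
        finite = np.isfinite(vals)
        conv = np.full_like(vals, np.nan)
        conv[finite] = np.asarray(m_to_beta(vals[finite]))
        vals = conv

    stat, p, _, d0, s0_sq = moderated_t(vals, labels)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    is_dmp = np.where(ok, q < fdr, False).astype(bool)
    table = pd.DataFrame(
        {"stat": stat, "p": p, "q": q, "is_dmp": is_dmp},
        index=matrix.probe_ids,
    )
    return DmpResult(table=table, fdr=fdr, d0=d0, s0_sq=s0_sq, scale=scale)


def count_true_positives(train: DmpResult, test: DmpResult,
                         require_sign: bool = True) -> int:
    """Count training DMPs validated in an independent test set.

    A training DMP is validated when it is also a DMP in the test result
    (same FDR rule) and, when ``require_sign``, the effect direction is
    concordant.
    """
    common = train.dmp_ids.intersection(test.dmp_ids)
    if not require_sign:
        return len(common)
    sign_train = np.sign(train.table.loc[common, "stat"])
    sign_test = np.sign(test.table.loc[common, "stat"])
    return int((sign_train == sign_test).sum())


def ppv(n_tp: int, n_dmp: int) -> tuple[float, float]:
    """Positive predictive value nTP / nDMP.

    Returns (full-precision value, value rounded half-up to 2 decimals).
    """
    if n_dmp <= 0:
        raise ValueError("PPV undefined for n_dmp = 0")
    if not 0 <= n_tp <= n_dmp:
        raise ValueError("require 0 <= n_tp <= n_dmp")
    value = n_tp / n_dmp
    rounded = float((Decimal(n_tp) / Decimal(n_dmp)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP))
    return value, rounded


# ---------------------------------------------------------------------------
# sample quality control


def qc_filter_samples(detection_p: pd.DataFrame, params: QcParams
                      ) -> tuple[list[str], float]:
    """Drop samples whose bad-probe fraction exceeds tau_r.

    A probe is bad in a sample when its detection p-value is strictly
    greater than tau_p; a sample is dropped when its bad fraction is
    strictly greater than tau_r.  Returns (kept sample IDs, kept ratio).
    """
    p = detection_p.to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("detection p-values must lie in [0, 1]")
    bad_frac = (p > params.tau_p).mean(axis=0)
    keep = bad_frac <= params.tau_r
    kept = [str(s) for s in detection_p.columns[keep]]
    return kept, float(keep.mean())
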