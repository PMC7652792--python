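"""Synthetic 450K-like data with known ground truth.

The generator emulates the structure the normalization assumes: per-array
M-values drawn from a three-component Gaussian mixture over methylation
states, with the type II design showing a compressed dynamic range —
outer component means pulled toward zero (default +-2.6 against the type
I +-4) — plus replicate noise and, optionally, probes spiked with a group
difference for differential-methylation experiments.

A probe's latent state and its standard-normal draw are shared between
the type I and type II parameterizations, so the type II bias is exactly
a component-wise affine compression of the type I truth:

    m_II = mu_II[k] + (sigma_II[k] / sigma_I[k]) * (m_I - mu_I[k])

Setting ``mix_II = mix_I`` therefore makes the compression the identity.
A smooth tanh compression of the type I truth is available behind
``compression="sigmoid"`` as an alternative bias shape.  Replicate
columns within a replicate group share the latent truth and differ only
by i.i.d. Gaussian noise on the M scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import MethylMatrix

__all__ = ["MixtureSpec", "SimulationSpec", "simulate_array"]

DEFAULT_MIX_I = ((0.3, -4.0, 1.0), (0.3, 0.0, 1.0), (0.4, 4.0, 1.0))
DEFAULT_MIX_II = ((0.3, -2.6, 1.0), (0.3, 0.0, 1.0), (0.4, 2.6, 1.0))


@dataclass(frozen=True)
class MixtureSpec:
    """(weight, mean, sd) triplets of a probe type's M-value mixture."""

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        w = np.array([c[0] for c in self.components])
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValueError("mixture weights must be a probability simplex")
        if any(c[2] <= 0 for c in self.components):
            raise ValueError("mixture sds must be positive")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c[2] for c in self.components])


@dataclass
class SimulationSpec:
    """Conditions of one simulated experiment.

    Defaults are the canonical M-scale mixture — outer states at +-4 for
    type I, compressed to +-2.6 for type II, unit component SDs, weights
    (0.3, 0.3, 0.4) — with three replicate-free samples and no spiked
    probes.  ``group_labels`` (0/1 per sample) drive the spike: the
    ``n_spiked`` chosen probes are shifted by ``effect_size`` M-units in
    label-1 samples.  ``n_replicate_groups`` partitions the samples
    round-robin into groups sharing the latent truth.
    """

    n_typeI: int = 20_000
    n_typeII: int = 50_000
    mix_I: MixtureSpec = field(default_factory=lambda: MixtureSpec(DEFAULT_MIX_I))
    mix_II: MixtureSpec = field(default_factory=lambda: MixtureSpec(DEFAULT_MIX_II))
    n_samples: int = 3
    n_replicate_groups: int = 1
    replicate_noise_sd: float = 0.3
    n_spiked: int = 0
    effect_size: float = 0.0
    group_labels: tuple[int, ...] | None = None
    compression: str = "affine"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_typeI <= 0 or self.n_typeII <= 0:
            raise ValueError("probe counts must be positive")
        if self.n_samples < 1:
            raise ValueError("need at least one sample")
        if not 1 <= self.n_replicate_groups <= self.n_samples:
            raise ValueError("n_replicate_groups must lie in [1, n_samples]")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be >= 0")
        if not 0 <= self.n_spiked <= self.n_typeI + self.n_typeII:
            raise ValueError("n_spiked must lie in [0, total probes]")
        if len(self.mix_I.components) != len(self.mix_II.components):
            raise ValueError("mix_I and mix_II must have the same component count")
        if self.group_labels is not None:
            if len(self.group_labels) != self.n_samples:
                raise ValueError(
                    f"group_labels has {len(self.group_labels)} entries for "
                    f"{self.n_samples} samples"
                )
            if any(g not in (0, 1) for g in self.group_labels):
                raise ValueError("group_labels must be binary (0/1)")
        elif self.n_spiked > 0:
            raise ValueError("spiked probes require group_labels")
        if self.compression not in ("affine", "sigmoid"):
            raise ValueError("compression must be 'affine' or 'sigmoid'")

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        return json.dumps(d, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        for key in ("mix_I", "mix_II"):
            if key in d and not isinstance(d[key], MixtureSpec):
                comps = d[key]["components"] if isinstance(d[key], dict) else d[key]
                d[key] = MixtureSpec(tuple(tuple(c) for c in comps))
        if d.get("group_labels") is not None:
            d["group_labels"] = tuple(d["group_labels"])
        return cls(**d)


def _sigmoid_scale(mix_I: MixtureSpec, mix_II: MixtureSpec) -> float:
    """Scale c of the tanh compression c*tanh(x/c) matching the outer means."""
    target = float(np.max(np.abs(mix_II.means)))
    source = float(np.max(np.abs(mix_I.means)))
    if target >= source:
        raise ValueError("sigmoid compression needs |outer mu_II| < |outer mu_I|")
    return brentq(lambda c: c * np.tanh(source / c) - target, target + 1e-9, 1e6)


def simulate_array(spec: SimulationSpec) -> tuple[MethylMatrix, dict]:
    """Draw a probes x samples M-value matrix with known truth.

    Returns the matrix (scale "m", probe IDs ``tI_000001...`` /
    ``tII_000001...``) and a truth record holding per-probe component
    memberships, the latent noise-free values per replicate group, the
    spiked probe IDs and the sample-to-group assignments.
    """
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_typeI, spec.n_typeII
    n_probes = n1 + n2
    probe_ids = np.array(
        [f"tI_{i + 1:06d}" for i in range(n1)]
        + [f"tII_{i + 1:06d}" for i in range(n2)]
    )
    probe_type = pd.Series(np.r_[np.repeat("I", n1), np.repeat("II", n2)],
                           index=pd.Index(probe_ids, name="probe_id"),
                           name="probe_type")

    rep_group = np.arange(spec.n_samples) % spec.n_replicate_groups
    labels = (np.zeros(spec.n_samples, dtype=int) if spec.group_labels is None
              else np.asarray(spec.group_labels, dtype=int))

    spiked = np.zeros(n_probes, dtype=bool)
    if spec.n_spiked > 0:
        spiked[rng.choice(n_probes, size=spec.n_spiked, replace=False)] = True

    if spec.compression == "sigmoid":
        sig_c = _sigmoid_scale(spec.mix_I, spec.mix_II)

    # latent truth per replicate group: shared component label and
    # standard-normal draw; spiking shifts the type-I-scale truth before
    # the design compression is applied
    k_components = len(spec.mix_I.components)
    comp = np.empty((n_probes, spec.n_replicate_groups), dtype=int)
    true_I = np.empty((n_probes, spec.n_replicate_groups))
    for g in range(spec.n_replicate_groups):
        comp_I = rng.choice(k_components, size=n1, p=spec.mix_I.weights)
        comp_II = rng.choice(k_components, size=n2, p=spec.mix_II.weights)
        comp[:, g] = np.r_[comp_I, comp_II]
        z = rng.standard_normal(n_probes)
        true_I[:, g] = spec.mix_I.means[comp[:, g]] + spec.mix_I.sds[comp[:, g]] * z

    values = np.empty((n_probes, spec.n_samples))
    type_II = np.r_[np.zeros(n1, dtype=bool), np.ones(n2, dtype=bool)]
    for j in range(spec.n_samples):
        g = rep_group[j]
        truth = true_I[:, g].copy()
        if labels[j] == 1:
            truth[spiked] += spec.effect_size
        col = truth.copy()
        if spec.compression == "affine":
            k = comp[type_II, g]
            col[type_II] = (spec.mix_II.means[k]
                            + (spec.mix_II.sds[k] / spec.mix_I.sds[k])
                            * (truth[type_II] - spec.mix_I.means[k]))
        else:
            col[type_II] = sig_c * np.tanh(truth[type_II] / sig_c)
        if spec.replicate_noise_sd > 0:
            col = col + rng.normal(0.0, spec.replicate_noise_sd, n_probes)
        values[:, j] = col

    sample_ids = [f"s{j + 1:02d}" for j in range(spec.n_samples)]
    matrix = MethylMatrix(
        values=pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                            columns=sample_ids),
        probe_type=probe_type,
        scale="m",
    )
    truth_record = {
        "component": comp[:, 0].tolist() if spec.n_replicate_groups == 1
        else comp.tolist(),
        "spiked_probes": probe_ids[spiked].tolist(),
        "replicate_group": rep_group.tolist(),
        "group_labels": labels.tolist(),
        "sample_ids": sample_ids,
        "true_m_typeI_scale": true_I[:, 0].tolist() if n_probes <= 10_000 else None,
    }
    return matrix, truth_record
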