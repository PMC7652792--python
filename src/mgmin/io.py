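"""Matrix and annotation I/O.

A methylation matrix is a probes x samples table of beta- or M-values.
The container pairs it with the per-probe Infinium design type (I or II)
— the 450K array mixes ~135k type I and ~350k type II probes — and an
explicit declaration of the value scale, so that downstream code never
has to guess whether a number is a beta in [0, 1] or an M-value.

Supported on-disk formats are plain TSV/CSV (probe IDs in the first
column, sample IDs in the header) plus either a two-column
``probe_id<TAB>type`` annotation file or an Illumina manifest CSV from
which ``IlmnID`` and ``Infinium_Design_Type`` are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MethylMatrix",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "read_manifest_annotation",
    "write_annotation",
]

_VALID_SCALES = ("beta", "m")
_VALID_TYPES = ("I", "II")


@dataclass
class MethylMatrix:
    """Probe x sample methylation values with design-type annotation.

    Attributes
    ----------
    values
        DataFrame, rows indexed by probe ID, columns by sample ID.
        NaN marks missing cells.
    probe_type
        Series mapping every probe ID in ``values`` to "I" or "II".
    scale
        "beta" or "m"; conversions refuse to run when the declared scale
        does not match the requested operation.
    """

    values: pd.DataFrame
    probe_type: pd.Series
    scale: str
    sample_flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in _VALID_SCALES:
            raise ValueError(f"scale must be one of {_VALID_SCALES}, got {self.scale!r}")
        if self.values.empty:
            raise ValueError("matrix has no probes or no samples")
        missing = self.values.index.difference(self.probe_type.index)
        if len(missing) > 0:
            shown = ", ".join(map(str, missing[:10]))
            raise ValueError(
                f"{len(missing)} probes lack a design-type annotation: {shown}"
                + ("..." if len(missing) > 10 else "")
            )
        self.probe_type = self.probe_type.reindex(self.values.index)
        bad = ~self.probe_type.isin(_VALID_TYPES)
        if bad.any():
            offenders = ", ".join(map(str, self.probe_type.index[bad][:10]))
            raise ValueError(f"design type must be 'I' or 'II'; offending probes: {offenders}")
        if self.scale == "beta":
            vals = self.values.to_numpy(dtype=float)
            finite = np.isfinite(vals)
            if np.any(finite & ((vals < 0) | (vals > 1))):
                rows, cols = np.nonzero(finite & ((vals < 0) | (vals > 1)))
                pid = self.values.index[rows[0]]
                sid = self.values.columns[cols[0]]
                raise ValueError(
                    f"beta values must lie in [0, 1]; first offender: probe {pid}, "
                    f"sample {sid}, value {vals[rows[0], cols[0]]!r}"
                )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def type_mask(self, probe_type: str) -> np.ndarray:
        if probe_type not in _VALID_TYPES:
            raise ValueError(f"probe_type must be 'I' or 'II', got {probe_type!r}")
        return (self.probe_type == probe_type).to_numpy()

    def copy_with(self, values: pd.DataFrame, scale: str | None = None) -> "MethylMatrix":
        return MethylMatrix(
            values=values,
            probe_type=self.probe_type.copy(),
            scale=self.scale if scale is None else scale,
            sample_flags=dict(self.sample_flags),
        )


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_annotation(path) -> pd.Series:
    """Read a two-column ``probe_id<TAB>type`` annotation (header optional)."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"annotation {path} must have two columns")
    # tolerate a header row
    if str(df.iloc[0, 1]).strip() not in _VALID_TYPES:
        df = df.iloc[1:]
    ann = pd.Series(
        df.iloc[:, 1].str.strip().to_numpy(),
        index=pd.Index(df.iloc[:, 0].str.strip(), name="probe_id"),
        name="probe_type",
    )
    bad = ~ann.isin(_VALID_TYPES)
    if bad.any():
        raise ValueError(
            f"annotation types must be 'I' or 'II'; offending probes: "
            f"{', '.join(map(str, ann.index[bad][:10]))}"
        )
    return ann


def read_manifest_annotation(path) -> pd.Series:
    """Extract probe types from an Illumina manifest CSV.

    Uses the ``IlmnID`` and ``Infinium_Design_Type`` columns; any banner
    lines before the header row (as in the vendor's manifest files) are
    skipped.
    """
    path = Path(path)
    with open(path) as fh:
        skip = 0
        for line in fh:
            cols = [c.strip() for c in line.rstrip("\n").split(",")]
            if "IlmnID" in cols and "Infinium_Design_Type" in cols:
                break
            skip += 1
        else:
            raise ValueError(
                f"manifest {path} lacks IlmnID / Infinium_Design_Type columns"
            )
    df = pd.read_csv(path, skiprows=skip, dtype=str)
    ann = pd.Series(
        df["Infinium_Design_Type"].str.strip().to_numpy(),
        index=pd.Index(df["IlmnID"].str.strip(), name="probe_id"),
        name="probe_type",
    )
    bad = ~ann.isin(_VALID_TYPES)
    if bad.any():
        ann = ann[~bad]  # manifests list control rows with blank design type
    if ann.empty:
        raise ValueError(f"manifest {path} contains no typed probes")
    return ann


def read_matrix(path, annotation_path, scale: str) -> MethylMatrix:
    """Load a probes x samples matrix plus its design-type annotation.

    The annotation file may be the two-column TSV or an Illumina manifest
    CSV (detected by its header).  Every probe in the matrix must be
    annotated; beta matrices are range-checked on load.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    values = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"],
                         float_precision="round_trip")
    if values.empty:
        raise ValueError(f"matrix {path} is empty")
    values.index = values.index.astype(str)
    values = values.astype(float)

    annotation_path = Path(annotation_path)
    with open(annotation_path) as fh:
        head = fh.read(65536)
    if "Infinium_Design_Type" in head:
        ann = read_manifest_annotation(annotation_path)
    else:
        ann = read_annotation(annotation_path)
    return MethylMatrix(values=values, probe_type=ann, scale=scale)


def write_matrix(matrix: MethylMatrix, path, sep: str = "\t") -> None:
    """Write the matrix with full double precision; NaN serialises as NA.

    Values are written with Python's shortest round-trip float repr, so a
    read/write cycle is bit-identical.
    """
    matrix.values.to_csv(Path(path), sep=sep, na_rep="NA", index_label="probe_id")


def write_annotation(probe_type: pd.Series, path) -> None:
    probe_type.rename("probe_type").to_csv(Path(path), sep="\t", header=False)
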