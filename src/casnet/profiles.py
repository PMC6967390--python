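"""Abundance-profile I/O, marker normalization, prevalence filtering and labeling.

The central object is :class:`AbundanceMatrix`, a families x samples table of
non-negative reals.  Columns are normalized by the per-sample median abundance
of a set of single-copy marker families, turning relative abundances into
average copy numbers per genome; rare families are then removed by a
prevalence filter before network inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Label",
    "AbundanceMatrix",
    "MarkerSet",
    "read_profile_table",
    "write_profile_table",
    "normalize_by_markers",
    "filter_prevalence",
    "label_from_keyword",
    "read_label_map",
    "write_label_map",
    "read_name_map",
]


class Label(str, Enum):
    """Per-family annotation state."""

    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    UNANNOTATED = "UNANNOTATED"


LabelVector = dict  # family_id -> Label; plain dict keeps ordering and is cheap


@dataclass(frozen=True)
class AbundanceMatrix:
    """Families x samples non-negative abundance table.

    Parameters
    ----------
    family_ids : list of str
        Unique row identifiers, order preserved.
    sample_ids : list of str
        Unique column identifiers, order preserved.
    values : ndarray of shape (n_families, n_samples)
        Non-negative abundances.
    """

    family_ids: tuple
    sample_ids: tuple
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "family_ids", tuple(self.family_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if values.shape != (len(self.family_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {values.shape} vs "
                f"{len(self.family_ids)} families x {len(self.sample_ids)} samples"
            )
        if len(set(self.family_ids)) != len(self.family_ids):
            raise ValueError("duplicate family ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite abundance values")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at family {self.family_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.family_ids), columns=list(self.sample_ids)
        )

    def row(self, family_id: str) -> np.ndarray:
        return self.values[self.family_ids.index(family_id)]


@dataclass(frozen=True)
class MarkerSet:
    """Identifiers of single-copy marker families used for normalization."""

    marker_family_ids: frozenset

    def __post_init__(self):
        object.__setattr__(
            self, "marker_family_ids", frozenset(self.marker_family_ids)
        )
        if not self.marker_family_ids:
            raise ValueError("marker set is empty")


def read_profile_table(path) -> AbundanceMatrix:
    """Read a TSV abundance table (header row = sample ids, first column = family ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate family id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            fam = df.index[parsed.isna()][0]
            raise ValueError(
                f"{path}: non-numeric value at family {fam!r}, sample {col!r}"
            )
        values[:, j] = parsed.to_numpy()
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative value at family {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return AbundanceMatrix(tuple(df.index), tuple(df.columns), values)


def write_profile_table(matrix: AbundanceMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="family_id")


def normalize_by_markers(matrix: AbundanceMatrix, markers: MarkerSet) -> AbundanceMatrix:
    """Divide every sample column by the median abundance of the marker families.

    The result is interpretable as average copy number per genome in a sample.
    Markers absent from the matrix are logged and skipped; it is an error if
    none remain or if any sample's marker median is zero.
    """
    present = [f for f in matrix.family_ids if f in markers.marker_family_ids]
    missing = markers.marker_family_ids - set(present)
    if missing:
        logger.warning(
            "%d marker families absent from matrix (e.g. %s)",
            len(missing),
            sorted(missing)[:3],
        )
    if not present:
        raise ValueError("no marker families found in the abundance matrix")
    idx = [matrix.family_ids.index(f) for f in present]
    medians = np.median(matrix.values[idx, :], axis=0)
    if np.any(medians <= 0):
        bad = matrix.sample_ids[int(np.argmax(medians <= 0))]
        raise ValueError(f"marker median is zero in sample {bad!r}")
    return AbundanceMatrix(
        matrix.family_ids, matrix.sample_ids, matrix.values / medians[None, :]
    )


def filter_prevalence(matrix: AbundanceMatrix, min_frac: float = 0.10) -> AbundanceMatrix:
    """Drop families present (abundance > 0) in less than ``min_frac`` of samples.

    The boundary is inclusive: a family present in exactly ``min_frac`` of
    samples is retained.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    frac = np.mean(matrix.values > 0, axis=1)
    keep = frac >= min_frac
    return AbundanceMatrix(
        tuple(f for f, k in zip(matrix.family_ids, keep) if k),
        matrix.sample_ids,
        matrix.values[keep, :],
    )


def label_from_keyword(
    name_map: Mapping[str, Iterable[str]],
    annotated: Iterable[str],
    keyword: str = "CRISPR",
    case_sensitive: bool = True,
) -> LabelVector:
    """Label each family POSITIVE if any of its protein names contains ``keyword``.

    Families without a keyword match are NEGATIVE when in ``annotated``,
    UNANNOTATED otherwise.
    """
    if not keyword:
        raise ValueError("keyword must be non-empty")
    annotated = set(annotated)
    needle = keyword if case_sensitive else keyword.lower()
    labels: LabelVector = {}
    for family, names in name_map.items():
        hit = any(
            needle in (name if case_sensitive else name.lower()) for name in names
        )
        if hit:
            labels[family] = Label.POSITIVE
        elif family in annotated:
            labels[family] = Label.NEGATIVE
        else:
            labels[family] = Label.UNANNOTATED
    return labels


def read_label_map(path) -> LabelVector:
    """Read a two-column TSV (family_id, label)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["family_id", "label"], dtype=str)
    out: LabelVector = {}
    for fam, lab in zip(df["family_id"], df["label"]):
        if fam in out:
            raise ValueError(f"duplicate family id {fam!r} in label map")
        out[fam] = Label(lab)
    return out


def write_label_map(labels: LabelVector, path) -> None:
    with open(path, "w") as fh:
        for fam, lab in labels.items():
            fh.write(f"{fam}\t{lab.value}\n")


def read_name_map(path) -> dict:
    """Read a two-column TSV (family_id, protein name), one row per name."""
    df = pd.read_csv(path, sep="\t", header=None, names=["family_id", "name"], dtype=str)
    out: dict = {}
    for fam, name in zip(df["family_id"], df["name"]):
        out.setdefault(fam, set())
        if isinstance(name, str):
            out[fam].add(name)
    return out
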