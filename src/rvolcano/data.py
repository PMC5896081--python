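"""Core data containers, delimited-text I/O, and auto-scaling.

The package operates on a metabolite abundance matrix ``X = (x_ij)`` with
``p`` metabolites in rows and ``n`` samples in columns, together with a
two-group design assigning every sample to either the control or the
disease group.  Matrices are read from and written to plain TSV/CSV with
sample identifiers in the first row and metabolite identifiers in the
first column.

Missing values are rejected at load time: the downstream statistics have
no missing-value rule, and silently imputing would change the test.
Users must impute (or filter) upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("rvolcano")

CONTROL = "control"
DISEASE = "disease"

#: smallest admissible group: sample variance needs g-1 >= 2 to be a useful
#: scale and cross-validation must be able to hold one fold out
MIN_GROUP_SIZE = 3


class TableFormatError(ValueError):
    """An input table violates the expected layout (bad cell, duplicate id, ...)."""


class DesignError(ValueError):
    """A group design is invalid (unknown label, missing sample, tiny group)."""


@dataclass(frozen=True)
class AbundanceMatrix:
    """Metabolites x samples intensity matrix with row/column identifiers.

    Parameters
    ----------
    values
        Real matrix of shape ``(p, n)``; every entry must be finite.
    metabolite_ids
        ``p`` unique row identifiers.
    sample_ids
        ``n`` unique column identifiers.
    """

    values: np.ndarray
    metabolite_ids: tuple
    sample_ids: tuple

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise TableFormatError(f"abundance matrix must be 2-D, got ndim={values.ndim}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "metabolite_ids", tuple(str(m) for m in self.metabolite_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        p, n = values.shape
        if len(self.metabolite_ids) != p:
            raise TableFormatError(
                f"{len(self.metabolite_ids)} metabolite ids for {p} rows"
            )
        if len(self.sample_ids) != n:
            raise TableFormatError(f"{len(self.sample_ids)} sample ids for {n} columns")
        for kind, ids in (("metabolite", self.metabolite_ids), ("sample", self.sample_ids)):
            seen: set = set()
            for name in ids:
                if name in seen:
                    raise TableFormatError(f"duplicate {kind} identifier {name!r}")
                seen.add(name)
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise TableFormatError(
                "non-finite value at metabolite "
                f"{self.metabolite_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def p(self) -> int:
        """Number of metabolites (rows)."""
        return self.values.shape[0]

    @property
    def n(self) -> int:
        """Number of samples (columns)."""
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.metabolite_ids, name="metabolite_id"),
            columns=list(self.sample_ids),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        return cls(df.to_numpy(dtype=float), tuple(df.index), tuple(df.columns))


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of each sample to the control or the disease group.

    ``group_of`` maps sample id to the canonical labels ``"control"`` /
    ``"disease"``.  The control group holds ``g1`` subjects and the disease
    group the remaining ``n - g1``.
    """

    group_of: Mapping[str, str]

    def __post_init__(self) -> None:
        group_of = dict(self.group_of)
        object.__setattr__(self, "group_of", group_of)
        for sample, label in group_of.items():
            if label not in (CONTROL, DISEASE):
                raise DesignError(f"sample {sample!r} has unknown group label {label!r}")
        for label in (CONTROL, DISEASE):
            size = sum(1 for v in group_of.values() if v == label)
            if size < MIN_GROUP_SIZE:
                raise DesignError(
                    f"group {label!r} has {size} samples; at least {MIN_GROUP_SIZE} required"
                )

    @property
    def control_count(self) -> int:
        """g1, the number of control subjects."""
        return sum(1 for v in self.group_of.values() if v == CONTROL)

    @property
    def disease_count(self) -> int:
        """n - g1, the number of disease subjects."""
        return sum(1 for v in self.group_of.values() if v == DISEASE)

    def indices(self, sample_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Column indices of the control and disease samples in ``sample_ids``.

        Raises :class:`DesignError` if any sample lacks an assignment.
        """
        ctrl, dis = [], []
        for j, sample in enumerate(sample_ids):
            label = self.group_of.get(sample)
            if label is None:
                raise DesignError(f"sample {sample!r} is missing from the design")
            (ctrl if label == CONTROL else dis).append(j)
        return np.asarray(ctrl, dtype=int), np.asarray(dis, dtype=int)

    @classmethod
    def from_labels(cls, sample_ids: Iterable[str], labels: Iterable[str]) -> "GroupDesign":
        return cls(dict(zip((str(s) for s in sample_ids), labels)))


def read_abundance_table(source, delimiter: str = "\t", transpose: bool = False) -> AbundanceMatrix:
    """Read a metabolites-by-samples table from delimited text.

    First row: sample identifiers; first column: metabolite identifiers;
    all remaining cells numeric.  ``transpose=True`` flips a
    samples-in-rows file into the canonical orientation.
    """
    try:
        df = pd.read_csv(source, sep=delimiter, index_col=0, header=0,
                         dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise TableFormatError(f"malformed table: {exc}") from exc
    if transpose:
        df = df.T
    for kind, idx in (("metabolite", df.index), ("sample", df.columns)):
        dup = idx[idx.duplicated()]
        if len(dup):
            raise TableFormatError(f"duplicate {kind} identifier {dup[0]!r}")
    bad = df.apply(pd.to_numeric, errors="coerce").isna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise TableFormatError(
            f"missing or non-numeric cell {df.iat[i, j]!r} at metabolite "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    # numpy's string parser round-trips floats exactly; pandas' default does not
    values = df.to_numpy(dtype=float)
    return AbundanceMatrix(values, tuple(df.index), tuple(df.columns))


def write_abundance_table(m: AbundanceMatrix, target, delimiter: str = "\t") -> None:
    """Write a matrix as delimited text; round-trips through
    :func:`read_abundance_table` with full float precision."""
    m.to_frame().to_csv(target, sep=delimiter)


def read_design(source, delimiter: str = "\t", control_label: str = CONTROL,
                disease_label: str = DISEASE) -> GroupDesign:
    """Read a two-column ``sample_id<TAB>group`` design file.

    Group labels must be one of the two given strings; they are mapped to
    the canonical ``control`` / ``disease`` labels.
    """
    df = pd.read_csv(source, sep=delimiter, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise DesignError("design file needs two columns: sample_id, group")
    samples = df.iloc[:, 0]
    labels = df.iloc[:, 1]
    mapping = {control_label: CONTROL, disease_label: DISEASE}
    group_of = {}
    for sample, label in zip(samples, labels):
        if label not in mapping:
            raise DesignError(
                f"sample {sample!r} has label {label!r}; expected "
                f"{control_label!r} or {disease_label!r}"
            )
        if sample in group_of:
            raise DesignError(f"sample {sample!r} listed twice in the design")
        group_of[sample] = mapping[label]
    return GroupDesign(group_of)


def write_design(d: GroupDesign, target, delimiter: str = "\t") -> None:
    pd.DataFrame(
        {"sample_id": list(d.group_of), "group": list(d.group_of.values())}
    ).to_csv(target, sep=delimiter, index=False)


def auto_scale(m: AbundanceMatrix) -> AbundanceMatrix:
    """Standardize each metabolite row to mean 0 and sample SD 1 (divisor n-1).

    Auto-scaling removes systematic between-metabolite intensity
    differences before multivariate displays; note that fold changes are
    not meaningful on auto-scaled data (means may become non-positive).
    """
    sd = m.values.std(axis=1, ddof=1)
    if np.any(sd == 0):
        i = int(np.argmax(sd == 0))
        raise TableFormatError(
            f"metabolite {m.metabolite_ids[i]!r} is constant; cannot auto-scale"
        )
    scaled = (m.values - m.values.mean(axis=1, keepdims=True)) / sd[:, None]
    return AbundanceMatrix(scaled, m.metabolite_ids, m.sample_ids)
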