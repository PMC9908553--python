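"""Core in-memory containers shared by every pipeline stage.

Expression data travels as a probe/gene x sample matrix with an optional
parallel matrix of per-probe per-sample detection p-values (the probability
that a probe's signal is indistinguishable from negative-control background
on the array). Phenotype data is a plain sample table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHENOTYPE_COLUMNS = [
    "sample_id",
    "diagnosis",
    "split",
    "age_months",
    "race",
    "ethnicity",
    "mutation_carrier",
    "severe_prenatal_event",
    "control_prenatal_event",
]


class SchemaError(ValueError):
    """An input table violates the expected schema."""


@dataclass
class ExpressionMatrix:
    """Probe (or gene) x sample intensity matrix.

    Parameters
    ----------
    values
        Intensities, rows indexed by probe/gene id, columns by sample id.
        Arbitrary linear scale unless a stage says otherwise.
    gene_ids
        Probe -> gene map aligned with ``values.index``. After collapsing to
        genes this is the identity map.
    detection_p
        Optional detection p-values, same shape and labels as ``values``.
    """

    values: pd.DataFrame
    gene_ids: pd.Series
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.gene_ids.index.equals(self.values.index):
            raise SchemaError("gene_ids index must match values index")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise SchemaError("detection_p and values must share shape")
            if not self.detection_p.index.equals(self.values.index):
                raise SchemaError("detection_p index must match values index")
            dp = self.detection_p.to_numpy()
            if dp.size and (np.nanmin(dp) < 0 or np.nanmax(dp) > 1):
                raise SchemaError("detection p-values must lie in [0, 1]")
        if self.values.columns.duplicated().any():
            raise SchemaError("duplicate sample ids in expression matrix")

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

    def subset_probes(self, probes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[probes],
            gene_ids=self.gene_ids.loc[probes],
            detection_p=None if self.detection_p is None else self.detection_p.loc[probes],
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values[list(samples)],
            gene_ids=self.gene_ids,
            detection_p=None if self.detection_p is None else self.detection_p[list(samples)],
        )


def validate_phenotype(table: pd.DataFrame) -> pd.DataFrame:
    """Check the phenotype table schema and return it unchanged.

    Raises :class:`SchemaError` naming the offending column/value.
    """
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"phenotype table missing columns: {missing}")
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"duplicate sample_id: {dup!r}")
    bad_dx = set(table["diagnosis"]) - {"ASD", "TD"}
    if bad_dx:
        raise SchemaError(f"diagnosis values must be ASD/TD, got {sorted(bad_dx)}")
    bad_split = set(table["split"]) - {"train", "test"}
    if bad_split:
        raise SchemaError(f"split values must be train/test, got {sorted(bad_split)}")
    if (table["age_months"] < 0).any():
        raise SchemaError("age_months contains negative values")
    return table


def labels_from_phenotype(phenotype: pd.DataFrame, sample_ids) -> np.ndarray:
    """Binary diagnosis labels (ASD=1, TD=0) aligned with ``sample_ids``."""
    dx = phenotype.set_index("sample_id")["diagnosis"].reindex(sample_ids)
    if dx.isna().any():
        missing = list(dx.index[dx.isna()])[:3]
        raise SchemaError(f"samples absent from phenotype table: {missing}")
    return (dx == "ASD").to_numpy(dtype=int)


@dataclass
class ContingencyTable2x2:
    """2x2 count table, rows = comparison groups, columns = (event, no event)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name} must be a non-negative integer, got {v}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is all zero")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn
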