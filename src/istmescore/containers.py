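"""Core in-memory containers shared across the pipeline.

All heavy data live in pandas objects; these classes only pin down the
orientation conventions (genes in rows, samples in columns) and the
invariants every stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALUE_SCALES = ("raw", "zscore", "minmax")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression grid.

    Parameters
    ----------
    data : pd.DataFrame
        Rows indexed by unique gene ids, columns by unique sample ids.
    value_scale : str
        One of ``raw``, ``zscore``, ``minmax``.  ``minmax`` asserts all
        values lie in [0, 1] (the contract NMF relies on).
    """

    data: pd.DataFrame
    value_scale: str = "raw"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame (genes x samples)")
        if self.value_scale not in VALUE_SCALES:
            raise ValueError(f"value_scale must be one of {VALUE_SCALES}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if not np.issubdtype(np.asarray(self.data.values).dtype, np.number):
            raise TypeError("expression values must be numeric")
        if self.value_scale == "minmax":
            v = self.data.values
            if v.size and (np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12):
                raise ValueError("value_scale='minmax' requires values in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[keep], value_scale=self.value_scale)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(samples)], value_scale=self.value_scale)


@dataclass
class GeneSet:
    """A named gene list (one GMT line)."""

    name: str
    description: str = ""
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g, None)
        self.genes = list(seen)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


class GeneSetCollection:
    """Ordered collection of uniquely named GeneSets."""

    def __init__(self, sets: list[GeneSet]):
        names = [s.name for s in sets]
        if len(set(names)) != len(names):
            raise ValueError("gene set names must be unique within a collection")
        self.sets = list(sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations with overall-survival endpoints.

    ``data`` is indexed by unique sample id and must contain ``os_time``
    (non-negative) and ``os_event`` (0/1); any further columns are treated
    as covariates.
    """

    data: pd.DataFrame
    n_dropped: int = 0

    REQUIRED = ("os_time", "os_event")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in clinical table")
        t = self.data["os_time"].astype(float)
        if (t < 0).any():
            raise ValueError("os_time must be non-negative")
        ev = self.data["os_event"]
        if not ev.isin([0, 1]).all():
            bad = sorted(set(ev[~ev.isin([0, 1])].tolist()))
            raise ValueError(f"os_event must be 0/1, found {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def os_time(self) -> np.ndarray:
        return self.data["os_time"].astype(float).values

    @property
    def os_event(self) -> np.ndarray:
        return self.data["os_event"].astype(int).values

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.REQUIRED]

    def subset(self, samples) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(samples)], n_dropped=0)
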