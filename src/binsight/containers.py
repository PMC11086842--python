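"""Core in-memory containers for expression data and its one-hot binarized form.

The canonical orientation everywhere in this package is samples-as-rows,
genes-as-columns.  Labels are binary: 1 = tumor (positive), 0 = normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "BinEntry", "BinMap", "BinarizedMatrix"]


@dataclass
class ExpressionMatrix:
    """A continuous samples x genes expression table with optional binary labels.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Non-negative expression values (typically log2(x+1)-scale RNA-seq).
    sample_ids, gene_ids : lists of unique strings.
    labels : optional ndarray of 0/1 ints, one per sample.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise ValueError("need at least 1 gene")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length does not match column count")
        if len(set(self.sample_ids)) != n:
            dupes = _duplicates(self.sample_ids)
            raise ValueError(f"duplicate sample IDs: {dupes}")
        if len(set(self.gene_ids)) != p:
            dupes = _duplicates(self.gene_ids)
            raise ValueError(f"duplicate gene IDs: {dupes}")
        if np.isnan(self.values).any():
            bad = [self.sample_ids[i] for i in
                   sorted(set(np.argwhere(np.isnan(self.values))[:, 0]))]
            raise ValueError(f"missing expression values in samples: {bad}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels length does not match sample count")
            uniq = set(np.unique(self.labels).tolist())
            if not uniq <= {0, 1}:
                raise ValueError(f"labels must be 0/1, found {sorted(uniq)}")
            self.labels = self.labels.astype(int)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   labels: np.ndarray | None = None) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), [str(s) for s in df.index],
                   [str(g) for g in df.columns], labels)


@dataclass(frozen=True)
class BinEntry:
    """One binary column: gene `gene_id` (source column `gene_index`),
    bin `bin_index` covering [lower, upper) — upper-closed for the top bin."""

    gene_index: int
    gene_id: str
    bin_index: int
    lower: float
    upper: float
    closed_upper: bool

    @property
    def column_id(self) -> str:
        return f"{self.gene_id}|bin{self.bin_index}"

    def interval_text(self, digits: int = 2) -> str:
        close = "]" if self.closed_upper else ")"
        return f"[{self.lower:.{digits}f}, {self.upper:.{digits}f}{close}"

    def __str__(self) -> str:  # pragma: no cover - convenience repr
        return f"{self.gene_id} in {self.interval_text()}"


class BinMap:
    """Bidirectional mapping between binary columns and (gene, value-range) pairs.

    Columns are ordered gene-major, bin-ascending: binary column ``j*K + k``
    is bin ``k`` of source gene ``j``.  Per gene the K equal-width intervals
    tile [0, 1]: [0,1/K), [1/K,2/K), ..., [(K-1)/K, 1].
    """

    def __init__(self, gene_ids: list[str], K: int):
        if K < 2:
            raise ValueError(f"K must be >= 2, got {K}")
        self.K = int(K)
        self.gene_ids = list(gene_ids)
        self.entries: list[BinEntry] = []
        for j, gid in enumerate(self.gene_ids):
            for k in range(self.K):
                self.entries.append(BinEntry(
                    gene_index=j, gene_id=gid, bin_index=k,
                    lower=k / self.K, upper=(k + 1) / self.K,
                    closed_upper=(k == self.K - 1)))

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, column: int) -> BinEntry:
        if not 0 <= column < len(self.entries):
            raise IndexError(
                f"binary column {column} out of range [0, {len(self.entries)})")
        return self.entries[column]

    @property
    def column_ids(self) -> list[str]:
        return [e.column_id for e in self.entries]

    def column_of(self, gene_id: str, bin_index: int) -> int:
        j = self.gene_ids.index(gene_id)
        if not 0 <= bin_index < self.K:
            raise IndexError(f"bin index {bin_index} out of range [0, {self.K})")
        return j * self.K + bin_index

    def to_dict(self) -> dict:
        return {"K": self.K, "gene_ids": self.gene_ids,
                "columns": [{"column": i, "column_id": e.column_id,
                             "gene": e.gene_id, "bin": e.bin_index,
                             "lower": e.lower, "upper": e.upper,
                             "closed_upper": e.closed_upper}
                            for i, e in enumerate(self.entries)]}

    @classmethod
    def from_dict(cls, d: dict) -> "BinMap":
        return cls(d["gene_ids"], d["K"])


@dataclass
class BinarizedMatrix:
    """0/1 samples x (genes*K) matrix with its BinMap and carried-through IDs.

    Invariant: within each gene's block of K columns every sample has exactly
    one 1 (the interval its normalized value falls in).
    """

    values: np.ndarray
    bin_map: BinMap
    sample_ids: list[str]
    labels: np.ndarray | None = None
    column_ids: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape[1] != len(self.bin_map):
            raise ValueError("column count does not match bin map")
        self.column_ids = self.bin_map.column_ids

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.column_ids)


def _duplicates(ids: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in ids:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out
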