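"""Delimited-text readers/writers and run manifests.

Matrices travel as TSV (CSV accepted), samples as rows with the sample ID in
the first column and gene IDs in the header; a ``transpose`` flag accepts
genes-as-rows dumps.  Labels come either from a designated column of the
matrix file or from a separate two-column (sample_id, label) file, and must
be literal 0/1 — string labels are refused rather than guessed at.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BinarizedMatrix, ExpressionMatrix

__all__ = ["read_expression_table", "read_labels", "write_matrix",
           "write_binarized", "write_report", "RunManifest"]


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_labels(path, sep: str | None = None) -> pd.Series:
    """Two-column (sample_id, label) file -> Series indexed by sample ID."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected exactly one label column, "
                         f"found {df.shape[1]}")
    s = df.iloc[:, 0]
    _validate_binary_labels(s, path)
    return s.astype(int)


def _validate_binary_labels(s: pd.Series, source) -> None:
    uniq = set(pd.unique(s).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(
            f"{source}: labels must be 0 (normal) or 1 (tumor); "
            f"found {sorted(map(str, uniq))}")


def read_expression_table(path, label_column: str | None = None,
                          label_path=None, sep: str | None = None,
                          transpose: bool = False) -> ExpressionMatrix:
    """Load a samples x genes table, validating IDs, values and labels.

    Rows containing missing expression values are rejected with their
    sample IDs listed (removal is an explicit load-time report, never
    silent).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    actual_sep = _sep_for(path, sep)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(actual_sep)[1:]
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        kind = "sample" if transpose else "gene"
        raise ValueError(f"{path}: duplicate {kind} IDs in header: {dupes}")
    df = pd.read_csv(path, sep=actual_sep, index_col=0)
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"{path}: label column {label_column!r} not found")
        lab = df[label_column]
        _validate_binary_labels(lab, path)
        labels = lab.astype(int).to_numpy()
        df = df.drop(columns=[label_column])
    non_numeric = [c for c in df.columns
                   if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric expression columns: "
                         f"{non_numeric[:5]}")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(
            f"{path}: samples without complete expression values "
            f"(remove or impute before loading): {bad}")
    if label_path is not None:
        lab = read_labels(label_path, sep=sep)
        missing = [s for s in df.index if s not in lab.index]
        if missing:
            raise ValueError(f"{label_path}: no label for samples {missing[:5]}")
        labels = lab.reindex(df.index).to_numpy()
    return ExpressionMatrix.from_frame(df, labels)


def write_matrix(matrix: ExpressionMatrix, path, sep: str | None = None) -> None:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_sep_for(path, sep),
                             index_label="sample_id")


def write_binarized(data: BinarizedMatrix, path, bin_map_path=None,
                    sep: str | None = None) -> None:
    """Binarized matrix as delimited text, bin map as a JSON sidecar."""
    path = Path(path)
    data.to_frame().to_csv(path, sep=_sep_for(path, sep),
                           index_label="sample_id")
    if bin_map_path is not None:
        Path(bin_map_path).write_text(
            json.dumps(data.bin_map.to_dict(), indent=1) + "\n")


def _to_records(report) -> pd.DataFrame:
    """Normalize the writable report types to a flat DataFrame."""
    from .explain import IntervalReport
    from .pipeline import ExperimentReport
    from .select import ScoredFeatures

    if isinstance(report, pd.DataFrame):
        return report
    if isinstance(report, ExperimentReport):
        return report.rows
    if isinstance(report, IntervalReport):
        return report.table
    if isinstance(report, ScoredFeatures):
        order = np.empty(len(report.rank), dtype=int)
        order[report.rank] = np.arange(len(report.rank))
        return pd.DataFrame({"column_id": report.column_ids,
                             "chi2": report.chi2, "rank": order})
    raise TypeError(f"cannot serialize {type(report).__name__}")


def write_report(report, path, format: str = "tsv") -> None:
    """Write a report as TSV (floats at 6 significant digits) or JSON
    (full precision).  Field order is deterministic."""
    df = _to_records(report)
    path = Path(path)
    try:
        if format == "tsv":
            df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        elif format == "json":
            path.write_text(json.dumps(df.to_dict(orient="records"),
                                       indent=1, default=_json_default) + "\n")
        else:
            raise ValueError(f"format must be 'tsv' or 'json', got {format!r}")
    except OSError as exc:
        raise OSError(f"failed writing report to {path}: {exc}") from exc


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config, input checksums, versions, seeds,
    and an index of every output file the run produced."""

    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)    # path -> sha256
    outputs: list = field(default_factory=list)   # relative paths
    seeds: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.versions:
            import sklearn
            import binsight
            self.versions = {"binsight": binsight.__version__,
                             "python": platform.python_version(),
                             "numpy": np.__version__,
                             "pandas": pd.__version__,
                             "scikit-learn": sklearn.__version__}

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _sha256(Path(path))

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        missing = [p for p in self.outputs if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest lists missing outputs: {missing}")
        Path(path).write_text(json.dumps(
            {"config": self.config, "inputs": self.inputs,
             "outputs": self.outputs, "seeds": self.seeds,
             "versions": self.versions}, indent=1, default=_json_default) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(config=d["config"], inputs=d["inputs"],
                   outputs=d["outputs"], seeds=d["seeds"],
                   versions=d["versions"])
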