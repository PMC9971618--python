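"""Reading and writing the delimited omics-matrix, mapping and annotation formats.

All matrices travel as :class:`OmicsLayer` objects: a features × samples
numeric matrix with ordered feature and sample identifiers and an optional
feature → gene map. Missing tokens (``NA``, ``NaN``, empty cell) are kept as
NaN on read and filtered later by :func:`pnmfmkl.diffexp.drop_missing_features`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OmicsLayer",
    "SampleAnnotation",
    "read_layer",
    "write_layer",
    "read_mapping",
    "read_annotation",
    "write_annotation",
    "intersect_samples",
    "write_report",
]

_MISSING_TOKENS = ("NA", "NaN", "nan", "")


class FormatError(ValueError):
    """Raised for malformed input tables (duplicate ids, non-numeric cells)."""


@dataclass
class OmicsLayer:
    """One platform's features × samples matrix.

    Parameters
    ----------
    layer_name : str
        Short identifier for the platform (e.g. ``"expr"``, ``"meth"``).
    values : ndarray of shape (n_features, n_samples)
        Numeric matrix; NaN marks missing entries.
    feature_ids : list of str
        Row identifiers, unique within the layer.
    sample_ids : list of str
        Column identifiers, unique.
    feature_to_gene : dict, optional
        Maps feature id → gene symbol. Identity when omitted.
    """

    layer_name: str
    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    feature_to_gene: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"layer {self.layer_name!r}: matrix shape {self.values.shape} "
                f"does not match {len(self.feature_ids)} features × "
                f"{len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError(f"layer {self.layer_name!r}: duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError(f"layer {self.layer_name!r}: duplicate sample ids")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_of(self, feature_id: str) -> str:
        """Gene symbol mapped to *feature_id* (identity if no map)."""
        if self.feature_to_gene is None:
            return feature_id
        return self.feature_to_gene.get(feature_id, feature_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "OmicsLayer":
        """Restrict to *sample_ids* in the given order."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OmicsLayer(
            self.layer_name,
            self.values[:, idx],
            self.feature_ids,
            list(sample_ids),
            self.feature_to_gene,
        )

    def subset_features(self, feature_ids: list[str]) -> "OmicsLayer":
        """Restrict to *feature_ids* in the given order."""
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return OmicsLayer(
            self.layer_name,
            self.values[idx, :],
            list(feature_ids),
            self.sample_ids,
            self.feature_to_gene,
        )


@dataclass
class SampleAnnotation:
    """Maps sample id → class label (categorical, ≥ 2 levels downstream)."""

    labels: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def subset(self, sample_ids: list[str]) -> "SampleAnnotation":
        return SampleAnnotation({s: self.labels[s] for s in sample_ids})

    def vector(self, sample_ids: list[str]) -> np.ndarray:
        return np.asarray([self.labels[s] for s in sample_ids], dtype=object)


def _delimiter_for(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def read_layer(
    path: str | Path,
    mapping_path: str | Path | None = None,
    layer_name: str | None = None,
    delimiter: str | None = None,
) -> OmicsLayer:
    """Read a delimited features × samples matrix.

    First column holds feature ids, header row holds sample ids; ``NA``,
    ``NaN`` and empty cells become missing values. Non-numeric body cells
    and duplicate ids raise :class:`FormatError`.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise FormatError(f"{path}: duplicate sample id {col!r}")
        seen.add(col)
    df = pd.read_csv(
        path, sep=sep, index_col=0, dtype=str, keep_default_na=False, na_values=[]
    )
    df.columns = header  # undo pandas' renaming of any duplicate columns
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col].to_numpy()
        cleaned = np.where(np.isin(raw, _MISSING_TOKENS), "nan", raw)
        try:
            values[:, j] = cleaned.astype(float)
        except ValueError:
            for i, cell in enumerate(cleaned):
                try:
                    float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric value {df.iloc[i, j]!r} at "
                        f"feature {df.index[i]!r}, sample {col!r}"
                    ) from None
            raise
    mapping = read_mapping(mapping_path, delimiter=delimiter) if mapping_path else None
    name = layer_name if layer_name is not None else path.stem
    return OmicsLayer(name, values, list(df.index), list(df.columns), mapping)


def write_layer(layer: OmicsLayer, path: str | Path, delimiter: str | None = None) -> None:
    """Write a layer back to delimited text, round-tripping full precision."""
    sep = _delimiter_for(path, delimiter)
    layer.to_frame().to_csv(path, sep=sep, float_format="%.17g", na_rep="NA")


def read_mapping(path: str | Path, delimiter: str | None = None) -> dict[str, str]:
    """Read a 2-column (feature_id, gene) table into a dict."""
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: mapping table needs 2 columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_annotation(path: str | Path, delimiter: str | None = None) -> SampleAnnotation:
    """Read a 2-column (sample_id, class) table."""
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: annotation table needs 2 columns")
    ids = list(df.iloc[:, 0])
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate sample id in annotation")
    return SampleAnnotation(dict(zip(ids, df.iloc[:, 1])))


def write_annotation(annot: SampleAnnotation, path: str | Path) -> None:
    sep = _delimiter_for(path, None)
    pd.DataFrame({"sample": annot.sample_ids, "label": [annot.labels[s] for s in annot.sample_ids]}).to_csv(
        path, sep=sep, header=False, index=False
    )


def intersect_samples(
    layers: list[OmicsLayer], annot: SampleAnnotation
) -> tuple[list[OmicsLayer], SampleAnnotation]:
    """Restrict every layer to the sorted common annotated sample set.

    The returned sample order is the lexicographically sorted intersection of
    all layers' samples with the annotated samples, so downstream matrices
    align deterministically regardless of input column order.
    """
    if not layers:
        raise ValueError("need at least one layer")
    common = set(annot.labels)
    for layer in layers:
        common &= set(layer.sample_ids)
    if not common:
        raise ValueError("sample intersection across layers and annotation is empty")
    order = sorted(common)
    return [layer.subset_samples(order) for layer in layers], annot.subset(order)


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a run report (nested dicts/lists of scalars) as JSON."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default) + "\n")
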