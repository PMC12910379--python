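"""Domain containers and I/O for multi-omics matrices, edge lists and clinical tables.

An omics *layer* is one molecular modality (mRNA expression, miRNA expression,
DNA methylation, ...) stored as a non-negative feature-by-sample matrix.  A
:class:`MultiOmicsDataset` is an ordered collection of layers measured on the
same samples.  Preprocessing mirrors the standard pipeline for network-
regularized NMF on such data: intersect samples across layers, drop
uninformative features, optionally restrict to network-covered features, cap
dimensionality by variance, and scale each feature row by its maximum so
values lie in [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("xintnmf")

__all__ = [
    "OmicsLayer",
    "MultiOmicsDataset",
    "ClinicalTable",
    "read_omics_matrix",
    "read_edge_list",
    "read_clinical",
    "preprocess",
]


def _detect_sep(path: str | Path, sep: str | None) -> str:
    """Auto-detect tab vs comma from the first line unless a delimiter is given."""
    if sep is not None:
        return sep
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


@dataclass
class OmicsLayer:
    """One feature-by-sample omics matrix X(d), non-negative by contract."""

    layer_id: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"layer {self.layer_id!r}: values must be 2-D")
        m, n = self.values.shape
        if m != len(self.feature_ids) or n != len(self.sample_ids):
            raise ValueError(
                f"layer {self.layer_id!r}: shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != m:
            raise ValueError(f"layer {self.layer_id!r}: duplicate feature IDs")
        if len(set(self.sample_ids)) != n:
            raise ValueError(f"layer {self.layer_id!r}: duplicate sample IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"layer {self.layer_id!r}: non-finite values present")
        if np.any(self.values < 0):
            raise ValueError(
                f"layer {self.layer_id!r}: negative entries violate the "
                "non-negativity contract of NMF input"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_features(self, index: np.ndarray) -> "OmicsLayer":
        return OmicsLayer(
            self.layer_id,
            [self.feature_ids[i] for i in index],
            list(self.sample_ids),
            self.values[index, :],
        )

    def select_samples(self, index: np.ndarray) -> "OmicsLayer":
        return OmicsLayer(
            self.layer_id,
            list(self.feature_ids),
            [self.sample_ids[i] for i in index],
            self.values[:, index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class MultiOmicsDataset:
    """Ordered omics layers sharing one sample axis; M = total feature count."""

    layers: list[OmicsLayer]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("dataset needs at least one layer")
        ref = self.layers[0].sample_ids
        for layer in self.layers[1:]:
            if layer.sample_ids != ref:
                raise ValueError(
                    f"layer {layer.layer_id!r} sample IDs differ from "
                    f"layer {self.layers[0].layer_id!r} (order included)"
                )
        ids = [l.layer_id for l in self.layers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate layer IDs")

    @property
    def D(self) -> int:
        return len(self.layers)

    @property
    def M(self) -> int:
        return sum(l.n_features for l in self.layers)

    @property
    def n_samples(self) -> int:
        return self.layers[0].n_samples

    @property
    def sample_ids(self) -> list[str]:
        return self.layers[0].sample_ids

    @property
    def layer_ids(self) -> list[str]:
        return [l.layer_id for l in self.layers]

    def layer(self, layer_id: str) -> OmicsLayer:
        for l in self.layers:
            if l.layer_id == layer_id:
                return l
        raise KeyError(layer_id)

    def stacked(self) -> np.ndarray:
        """Concatenation of all layers along the feature axis (M x N)."""
        return np.vstack([l.values for l in self.layers])

    def select_samples(self, index: Sequence[int] | np.ndarray) -> "MultiOmicsDataset":
        index = np.asarray(index)
        return MultiOmicsDataset([l.select_samples(index) for l in self.layers])

    def select_samples_by_id(self, sample_ids: Sequence[str]) -> "MultiOmicsDataset":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return self.select_samples(np.array([pos[s] for s in sample_ids]))


@dataclass
class ClinicalTable:
    """Per-sample phenotype label and/or survival record (time, event)."""

    data: pd.DataFrame  # index = sample_id; optional columns label, time, event

    def __post_init__(self) -> None:
        extra = set(self.data.columns) - {"label", "time", "event"}
        if extra:
            raise ValueError(f"unexpected clinical columns: {sorted(extra)}")
        if "time" in self.data:
            t = self.data["time"].dropna()
            if (t < 0).any():
                raise ValueError("negative survival time")
        if "event" in self.data and "time" not in self.data:
            raise ValueError("event column requires a time column")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def aligned_labels(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Binary labels for the given samples; NaN where missing."""
        return self.data.reindex(sample_ids)["label"].to_numpy(dtype=float)

    def aligned_survival(self, sample_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        sub = self.data.reindex(sample_ids)
        return sub["time"].to_numpy(dtype=float), sub["event"].to_numpy(dtype=float)

    def check_against(self, dataset: MultiOmicsDataset) -> list[str]:
        """Warn about clinical samples absent from the dataset; they are kept
        in the table but excluded from downstream analyses."""
        missing = [s for s in self.sample_ids if s not in set(dataset.sample_ids)]
        if missing:
            warnings.warn(
                f"{len(missing)} clinical samples not present in the omics dataset; "
                "they will be ignored downstream",
                stacklevel=2,
            )
        return missing


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_omics_matrix(path: str | Path, layer_id: str, sep: str | None = None) -> OmicsLayer:
    """Read a feature-by-sample matrix from delimited text.

    The header row holds sample IDs and the first column feature IDs.
    Delimiter is auto-detected among tab/comma unless ``sep`` is given.
    """
    sep = _detect_sep(path, sep)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed matrix file {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature IDs in {path}: {dups[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric entry in {path}: {exc}") from exc
    return OmicsLayer(layer_id, [str(i) for i in df.index], [str(c) for c in df.columns], values)


def read_edge_list(path: str | Path, sep: str | None = None) -> list[tuple[str, str]]:
    """Read a two-column edge list; de-duplicates unordered pairs, drops self-pairs."""
    sep = _detect_sep(path, sep)
    pairs: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(sep) if sep != "\t" else line.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected exactly 2 columns, got {len(fields)}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                continue  # no self-interactions
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            pairs.append((a, b))
    return pairs


def read_clinical(path: str | Path, sep: str | None = None) -> ClinicalTable:
    """Read a clinical table with a sample_id column and any of label/time/event."""
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    df = df.set_index("sample_id")
    keep = [c for c in ("label", "time", "event") if c in df.columns]
    if not keep:
        raise ValueError(f"{path}: need at least one of label/time/event columns")
    df = df[keep].apply(pd.to_numeric)
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.info("clinical table %s: %d missing values", path, n_missing)
    return ClinicalTable(df)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    dataset: MultiOmicsDataset | Sequence[OmicsLayer],
    network_feature_ids: Mapping[str, set[str]] | None = None,
    max_features: Mapping[str, int] | None = None,
) -> MultiOmicsDataset:
    """Standard preprocessing pipeline, idempotent by construction.

    1. intersect samples across layers (order of the first layer kept);
    2. drop zero-variance / all-zero features;
    3. for layers listed in ``network_feature_ids``, drop features absent
       from the given set;
    4. for layers listed in ``max_features``, keep the most variable features
       up to the cap (variance computed before scaling; ties by row order);
    5. divide every surviving row by its maximum (values end in [0, 1]).
    """
    network_feature_ids = network_feature_ids or {}
    max_features = max_features or {}
    in_layers = dataset.layers if isinstance(dataset, MultiOmicsDataset) else list(dataset)
    if not in_layers:
        raise ValueError("preprocess needs at least one layer")

    common = set(in_layers[0].sample_ids)
    for layer in in_layers[1:]:
        common &= set(layer.sample_ids)
    if not common:
        raise ValueError("no common samples across layers")
    order = [s for s in in_layers[0].sample_ids if s in common]

    out_layers = []
    for layer in in_layers:
        pos = {s: i for i, s in enumerate(layer.sample_ids)}
        layer = layer.select_samples(np.array([pos[s] for s in order]))

        variances = layer.values.var(axis=1)
        keep = (variances > 0) & (layer.values.max(axis=1) > 0)
        if layer.layer_id in network_feature_ids:
            allowed = network_feature_ids[layer.layer_id]
            keep &= np.array([f in allowed for f in layer.feature_ids])
        idx = np.flatnonzero(keep)
        cap = max_features.get(layer.layer_id)
        if cap is not None and len(idx) > cap:
            # stable sort keeps original row order among variance ties
            rank = np.argsort(-variances[idx], kind="stable")[:cap]
            idx = np.sort(idx[rank])
        if len(idx) == 0:
            raise ValueError(f"layer {layer.layer_id!r}: no features survive preprocessing")
        layer = layer.select_features(idx)

        row_max = layer.values.max(axis=1, keepdims=True)
        layer = replace(layer, values=layer.values / row_max)
        out_layers.append(layer)

    return MultiOmicsDataset(out_layers)
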