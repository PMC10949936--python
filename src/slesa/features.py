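"""Feature-vector containers, average pooling, PCA reduction and I/O.

A :class:`FeatureMatrix` holds ``k`` samples of fixed-length feature
vectors (typically deep features extracted from a CNN layer by an
external adapter) together with a binary class label per sample.
Internally the two classes are the tokens ``"m"`` (malignant, the
positive class) and ``"n"`` (benign).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

CLASS_MALIGNANT = "m"
CLASS_BENIGN = "n"
CLASSES = (CLASS_MALIGNANT, CLASS_BENIGN)

#: tokens accepted on input, mapped to the internal class labels
LABEL_ALIASES = {
    "malignant": CLASS_MALIGNANT,
    "benign": CLASS_BENIGN,
    "m": CLASS_MALIGNANT,
    "n": CLASS_BENIGN,
}


class FormatError(ValueError):
    """Raised when a feature file violates the expected layout."""


def normalize_label(token: str) -> str:
    try:
        return LABEL_ALIASES[str(token).strip().lower()]
    except KeyError:
        raise FormatError(f"unknown class label {token!r}; expected one of "
                          f"{sorted(LABEL_ALIASES)}") from None


@dataclass
class FeatureMatrix:
    """k samples x length-l feature vectors with binary labels.

    Parameters
    ----------
    values : (k, l) float array
        One feature vector per row; must be finite.
    labels : (k,) array of str
        Class per sample, ``"m"`` (malignant) or ``"n"`` (benign).
    sample_ids : (k,) array of str, optional
        Opaque identifiers; defaults to ``s0..s{k-1}``.
    """

    values: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("values must be a 2-D array with l >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contains non-finite entries")
        self.labels = np.asarray([normalize_label(t) for t in np.asarray(self.labels)],
                                 dtype=object)
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels must have exactly one entry per sample")
        if self.sample_ids is None:
            self.sample_ids = np.asarray([f"s{i}" for i in range(self.k)], dtype=object)
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
            if self.sample_ids.shape[0] != self.k:
                raise ValueError("sample_ids must have exactly one entry per sample")

    @property
    def k(self) -> int:
        """Number of samples."""
        return self.values.shape[0]

    @property
    def l(self) -> int:
        """Feature-vector length."""
        return self.values.shape[1]

    def subset(self, idx: Sequence[int] | np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(self.values[idx], self.labels[idx], self.sample_ids[idx])

    def classes_present(self) -> set[str]:
        return set(self.labels.tolist())


@dataclass(frozen=True)
class PoolingSpec:
    """Average-pooling target: reduce each row to ``target_length`` by
    non-overlapping window means of width ``floor(l / target_length)``."""

    target_length: int

    def __post_init__(self) -> None:
        if int(self.target_length) < 1:
            raise ValueError("target_length must be a positive integer")

    def window(self, l: int) -> int:
        if self.target_length > l:
            raise ValueError(f"target_length {self.target_length} exceeds "
                             f"feature length {l}")
        return l // self.target_length


def average_pool(features: FeatureMatrix, spec: PoolingSpec) -> FeatureMatrix:
    """Reduce each feature row to ``spec.target_length`` components.

    Component ``t`` of the output is the mean of the ``t``-th
    non-overlapping window of ``floor(l / target_length)`` input
    components; trailing remainder components are discarded.
    """
    lp = int(spec.target_length)
    w = spec.window(features.l)
    used = features.values[:, : lp * w]
    pooled = used.reshape(features.k, lp, w).mean(axis=2)
    return FeatureMatrix(pooled, features.labels, features.sample_ids)


def pca_reduce(
    train: FeatureMatrix,
    test: FeatureMatrix,
    n_components: int,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Project train and test onto the leading principal components of *train*.

    The PCA mean and components are fit on the training matrix only; the
    test matrix is projected with those fitted quantities, so no
    information flows from test to the fit.
    """
    n_components = int(n_components)
    bound = min(train.k, train.l)
    if not 1 <= n_components <= bound:
        raise ValueError(f"n_components must be in [1, {bound}], got {n_components}")
    if train.l != test.l:
        raise ValueError("train and test feature lengths differ")
    pca = PCA(n_components=n_components, svd_solver="full")
    zt = pca.fit_transform(train.values)
    zs = pca.transform(test.values)
    return (FeatureMatrix(zt, train.labels, train.sample_ids),
            FeatureMatrix(zs, test.labels, test.sample_ids))


# ---------------------------------------------------------------------------
# I/O: delimited text (CSV) and a binary array container (.npz)
# ---------------------------------------------------------------------------

def write_features(features: FeatureMatrix, path: str | Path, format: str = "csv") -> None:
    path = Path(path)
    if format == "csv":
        header = ["sample_id", "label"] + [f"f{i}" for i in range(features.l)]
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write(",".join(header) + "\n")
            for sid, lab, row in zip(features.sample_ids, features.labels,
                                     features.values):
                cells = [str(sid), str(lab)] + [format_float(v) for v in row]
                fh.write(",".join(cells) + "\n")
    elif format == "npz":
        np.savez(path, values=features.values,
                 labels=features.labels.astype(str),
                 sample_ids=features.sample_ids.astype(str))
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'npz'")


def format_float(v: float) -> str:
    return repr(float(v))


def read_features(path: str | Path, format: str = "csv") -> FeatureMatrix:
    path = Path(path)
    if format == "npz":
        with np.load(path, allow_pickle=False) as z:
            return FeatureMatrix(z["values"], z["labels"], z["sample_ids"])
    if format != "csv":
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'npz'")
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
        if len(header) < 3 or header[:2] != ["sample_id", "label"]:
            raise FormatError("header must start with 'sample_id,label,f0,...'")
        l = len(header) - 2
        ids, labels, rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(",")
            if len(cells) != l + 2:
                raise FormatError(f"row {lineno}: expected {l + 2} cells, "
                                  f"found {len(cells)}")
            ids.append(cells[0])
            labels.append(normalize_label_at(cells[1], lineno))
            try:
                rows.append([float(c) for c in cells[2:]])
            except ValueError:
                raise FormatError(f"row {lineno}: non-numeric feature cell") from None
    if not rows:
        raise FormatError("file contains no samples")
    return FeatureMatrix(np.asarray(rows), np.asarray(labels, dtype=object),
                         np.asarray(ids, dtype=object))


def normalize_label_at(token: str, lineno: int) -> str:
    try:
        return normalize_label(token)
    except FormatError as err:
        raise FormatError(f"row {lineno}: {err}") from None


def write_ground_truth(record: dict, path: str | Path) -> None:
    """Serialize a synthetic-data ground-truth record as JSON."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(record, default=default, indent=1),
                          encoding="utf-8")
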