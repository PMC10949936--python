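"""Ensemble residual log-likelihood classification.

Each test block is sparse-coded against a dictionary of labeled atoms.
The coefficients belonging to one class reconstruct the block with a
class-specific residual: ``r_m`` from malignant atoms, ``r_n`` from
benign atoms.  The block's log-likelihood score is

    LLS = -[log r_m - log r_n],

positive when the malignant atoms explain the block better.  The
ensemble score ELLS is the arithmetic mean of the block scores, and the
final prediction is its sign: positive -> malignant (class ``m``),
otherwise benign (class ``n``).

Three classifier entry points share this decision algebra:

* :func:`classify_blockboost` — block ``i`` coded against dictionary ``D_i``
* :func:`classify_patchsample` — every block coded against one pooled dictionary
* :func:`classify_src` — no block decomposition; whole (possibly
  PCA-reduced) vectors against a single dictionary

With a single block (``np = 1``) all three coincide exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .dictionaries import BlockDictionarySet, PatchDictionary
from .features import CLASS_BENIGN, CLASS_MALIGNANT, CLASSES, FeatureMatrix
from .sparse_coding import SparseCode, bpdn_solve

log = logging.getLogger(__name__)

#: floor applied to residuals before taking logs (guards exact reconstructions)
RESIDUAL_FLOOR = 1e-12

#: default relative noise margin: epsilon = 0.05 * ||y||_2 per block
DEFAULT_EPSILON = 0.05


@dataclass
class DecisionRecord:
    """Per-sample classification outcome.

    block_scores : np LLS values, one per block
    ells         : their arithmetic mean (the ensemble score)
    predicted    : 'm' (malignant) or 'n' (benign)
    residuals    : per block, the (r_m, r_n) pair
    """

    sample_id: str
    block_scores: np.ndarray
    ells: float
    predicted: str
    residuals: list[tuple[float, float]]
    true_label: str | None = None


def class_residual(
    y: np.ndarray,
    D: np.ndarray,
    x: SparseCode | np.ndarray,
    atom_labels: np.ndarray,
    target_class: str,
) -> float:
    """Residual ``||y - D delta_c(x)||_2`` keeping only ``target_class`` atoms.

    ``delta_c`` zeroes every coefficient whose atom is not labeled with the
    target class, so the residual measures how well that class's atoms alone
    reconstruct the block.
    """
    if target_class not in CLASSES:
        raise ValueError(f"unknown class {target_class!r}; expected one of {CLASSES}")
    coef = x.coefficients if isinstance(x, SparseCode) else np.asarray(x, dtype=float)
    atom_labels = np.asarray(atom_labels)
    if atom_labels.shape[0] != D.shape[1]:
        raise ValueError("atom_labels length must equal the dictionary atom count")
    masked = np.where(atom_labels == target_class, coef, 0.0)
    return float(np.linalg.norm(y - D @ masked))


def lls_score(r_m: float, r_n: float) -> float:
    """Block log-likelihood score ``-[log r_m - log r_n]``.

    Residuals are floored at 1e-12 before the log so exact one-class
    reconstructions produce large finite scores instead of infinities.
    """
    if r_m < 0 or r_n < 0:
        raise ValueError("residuals must be non-negative")
    return -(math.log(max(r_m, RESIDUAL_FLOOR)) - math.log(max(r_n, RESIDUAL_FLOOR)))


def ells_score(block_scores) -> float:
    """Ensemble score: arithmetic mean of the per-block LLS values."""
    scores = np.asarray(block_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("block_scores must be nonempty")
    return float(scores.mean())


def predict(ells: float) -> str:
    """Sign decision: positive ensemble score -> malignant, else benign.

    An exact zero is mapped to benign deterministically (and logged); the
    sign convention at zero is a tie-break, not a modeling statement.
    """
    if not math.isfinite(ells):
        raise ValueError("ells must be finite")
    if ells > 0:
        return CLASS_MALIGNANT
    if ells == 0:
        log.warning("ELLS tie (exactly 0); resolving to benign")
    return CLASS_BENIGN


def _resolve_epsilon(y: np.ndarray, epsilon: float, relative: bool) -> float:
    return float(epsilon) * float(np.linalg.norm(y)) if relative else float(epsilon)


def _decide(sample_id, true_label, blocks, dicts, labels_per_dict,
            epsilon, relative) -> DecisionRecord:
    scores, residuals = [], []
    for y, D, atom_labels in zip(blocks, dicts, labels_per_dict):
        code = bpdn_solve(y, D, _resolve_epsilon(y, epsilon, relative))
        r_m = class_residual(y, D, code, atom_labels, CLASS_MALIGNANT)
        r_n = class_residual(y, D, code, atom_labels, CLASS_BENIGN)
        scores.append(lls_score(r_m, r_n))
        residuals.append((r_m, r_n))
    ells = ells_score(scores)
    return DecisionRecord(str(sample_id), np.asarray(scores), ells,
                          predict(ells), residuals, true_label)


def classify_blockboost(
    test: FeatureMatrix,
    dicts: BlockDictionarySet,
    epsilon: float = DEFAULT_EPSILON,
    relative_epsilon: bool = True,
) -> list[DecisionRecord]:
    """Classify each test sample with one sparse coder per block index."""
    s, n_blk = dicts.s, dicts.n_blocks
    if test.l < s * n_blk:
        raise ValueError(f"test length {test.l} incompatible with "
                         f"s={s}, np={n_blk}")
    out = []
    for j in range(test.k):
        row = test.values[j]
        blocks = [row[i * s:(i + 1) * s] for i in range(n_blk)]
        out.append(_decide(test.sample_ids[j], test.labels[j], blocks,
                           dicts.blocks, [dicts.atom_labels] * n_blk,
                           epsilon, relative_epsilon))
    return out


def classify_patchsample(
    test: FeatureMatrix,
    dictionary: PatchDictionary,
    epsilon: float = DEFAULT_EPSILON,
    relative_epsilon: bool = True,
) -> list[DecisionRecord]:
    """Classify each test sample coding every block against the pooled dictionary."""
    s = dictionary.matrix.shape[0]
    n_blk = test.l // s
    if n_blk < 1:
        raise ValueError(f"test length {test.l} shorter than block length {s}")
    out = []
    for j in range(test.k):
        row = test.values[j]
        blocks = [row[i * s:(i + 1) * s] for i in range(n_blk)]
        out.append(_decide(test.sample_ids[j], test.labels[j], blocks,
                           [dictionary.matrix] * n_blk,
                           [dictionary.atom_labels] * n_blk,
                           epsilon, relative_epsilon))
    return out


def classify_src(
    test: FeatureMatrix,
    D: np.ndarray,
    atom_labels: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
    relative_epsilon: bool = True,
) -> list[DecisionRecord]:
    """Conventional SRC: whole vectors against a single dictionary (np = 1)."""
    if test.l != D.shape[0]:
        raise ValueError(f"test length {test.l} does not match dictionary "
                         f"dimension {D.shape[0]}")
    out = []
    for j in range(test.k):
        out.append(_decide(test.sample_ids[j], test.labels[j],
                           [test.values[j]], [D], [atom_labels],
                           epsilon, relative_epsilon))
    return out


def records_to_frame(records: list[DecisionRecord]):
    """Tidy per-block table: sample_id, block_index, lls, ells, predicted, true_label."""
    import pandas as pd

    rows = []
    for rec in records:
        for i, (lls, (r_m, r_n)) in enumerate(zip(rec.block_scores, rec.residuals)):
            rows.append({"sample_id": rec.sample_id, "block_index": i,
                         "lls": lls, "r_m": r_m, "r_n": r_n,
                         "ells": rec.ells, "predicted": rec.predicted,
                         "true_label": rec.true_label})
    return pd.DataFrame(rows)
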