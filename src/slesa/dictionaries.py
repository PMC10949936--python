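"""Dictionary construction for spatially localized sparse analysis.

Two decompositions of length-``l`` feature vectors into ``np = floor(l/s)``
blocks of length ``s`` are supported:

* **BlockBoost** — one dictionary per block index ``i``; dictionary ``D_i``
  has the ``i``-th block of every training sample as its columns, so block
  ``i`` of a test vector is coded only against block-``i`` atoms.
* **PatchSample** — a single pooled dictionary whose ``k * np`` atoms are
  all blocks of all training samples; every test block is coded against it.

Label-specific dictionary learning (K-SVD) is provided for the LS-SLESA /
LS-SRC variants: a compact dictionary is learned per class by alternating
orthogonal matching pursuit with sequential rank-1 singular-vector atom
updates, and the per-class dictionaries are concatenated with their class
labels attached to the atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import orthogonal_mp

from .features import FeatureMatrix


@dataclass(frozen=True)
class BlockSpec:
    """Block length ``s``; the number of blocks is ``np = floor(l / s)``.

    Components beyond ``np * s`` are discarded (there is never a partial
    block)."""

    s: int

    def __post_init__(self) -> None:
        if int(self.s) < 1:
            raise ValueError("block length s must be a positive integer")

    def n_blocks(self, l: int) -> int:
        if self.s > l:
            raise ValueError(f"block length s={self.s} exceeds feature length l={l}")
        return l // self.s


@dataclass
class BlockDictionarySet:
    """np index-specific dictionaries, each of shape (s, k)."""

    blocks: list[np.ndarray]
    atom_labels: np.ndarray
    normalized: bool
    s: int = field(init=False)
    k: int = field(init=False)

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.blocks}
        if len(shapes) != 1:
            raise ValueError("all block dictionaries must share one shape")
        self.s, self.k = self.blocks[0].shape
        if len(self.atom_labels) != self.k:
            raise ValueError("atom_labels must have one entry per training sample")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


@dataclass
class PatchDictionary:
    """One pooled dictionary of shape (s, k*np) with per-atom provenance.

    Atoms are ordered sample-major then block, matching the enumeration
    ``d_1^1 .. d_1^np, d_2^1, ..., d_k^np``; ``provenance[j]`` is the
    (sample_id, block_index) pair the atom was cut from.
    """

    matrix: np.ndarray
    atom_labels: np.ndarray
    provenance: list[tuple[str, int]]
    normalized: bool

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.atom_labels) or \
                self.matrix.shape[1] != len(self.provenance):
            raise ValueError("atom_labels and provenance must match atom count")


def split_blocks(features: FeatureMatrix, spec: BlockSpec) -> list[list[np.ndarray]]:
    """Cut each sample into ``np`` length-``s`` blocks.

    Block ``i`` of sample ``j`` is components ``[i*s, (i+1)*s)``; the
    trailing ``l - np*s`` components are discarded.
    """
    s = int(spec.s)
    n_blk = spec.n_blocks(features.l)
    out = []
    for row in features.values:
        out.append([row[i * s:(i + 1) * s].copy() for i in range(n_blk)])
    return out


def _normalize_columns(mat: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(mat, axis=0)
    zero = norms == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} zero atom(s) left unnormalized",
                      RuntimeWarning, stacklevel=3)
    safe = np.where(zero, 1.0, norms)
    return mat / safe


def _require_two_classes(features: FeatureMatrix) -> None:
    if features.k < 2 or len(features.classes_present()) < 2:
        raise ValueError("training set must contain at least two samples "
                         "covering both classes")


def build_block_dictionaries(
    features: FeatureMatrix,
    spec: BlockSpec,
    normalize: bool = True,
) -> BlockDictionarySet:
    """BlockBoost mode: one (s, k) dictionary per block index."""
    _require_two_classes(features)
    s = int(spec.s)
    n_blk = spec.n_blocks(features.l)
    blocks = []
    for i in range(n_blk):
        mat = features.values[:, i * s:(i + 1) * s].T.copy()
        blocks.append(_normalize_columns(mat) if normalize else mat)
    return BlockDictionarySet(blocks, features.labels.copy(), normalized=normalize)


def build_patch_dictionary(
    features: FeatureMatrix,
    spec: BlockSpec,
    normalize: bool = True,
) -> PatchDictionary:
    """PatchSample mode: a single (s, k*np) dictionary pooling every block."""
    _require_two_classes(features)
    s = int(spec.s)
    n_blk = spec.n_blocks(features.l)
    # cut and normalize per block exactly as the BlockBoost builder does, so
    # the np = 1 case is bit-identical to the single block dictionary
    per_block = []
    for i in range(n_blk):
        mat = features.values[:, i * s:(i + 1) * s].T.copy()
        per_block.append(_normalize_columns(mat) if normalize else mat)
    cols, labels, prov = [], [], []
    for j in range(features.k):
        for i in range(n_blk):
            cols.append(per_block[i][:, j])
            labels.append(features.labels[j])
            prov.append((str(features.sample_ids[j]), i))
    return PatchDictionary(np.column_stack(cols),
                           np.asarray(labels, dtype=object), prov,
                           normalized=normalize)


# ---------------------------------------------------------------------------
# K-SVD dictionary learning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KsvdSpec:
    """K-SVD hyperparameters.

    atoms_per_class : dictionary size learned for one class
    sparsity_T0     : OMP sparsity used during the coding stage
    iterations      : alternations of coding and atom updates
    seed            : seeds the initialization (random subset of samples)
    """

    atoms_per_class: int
    sparsity_T0: int = 5
    iterations: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.atoms_per_class) < 1:
            raise ValueError("atoms_per_class must be >= 1")
        if not 1 <= int(self.sparsity_T0) <= int(self.atoms_per_class):
            raise ValueError("sparsity_T0 must satisfy 1 <= T0 <= atoms_per_class")
        if int(self.iterations) < 0:
            raise ValueError("iterations must be non-negative")


def _omp_codes(D: np.ndarray, Y: np.ndarray, t0: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        X = orthogonal_mp(D, Y, n_nonzero_coefs=min(t0, D.shape[1]))
    if X.ndim == 1:
        X = X[:, None]
    return X


def ksvd_learn(
    features_one_class: FeatureMatrix | np.ndarray,
    spec: KsvdSpec,
    return_objective: bool = False,
):
    """Learn a unit-norm dictionary from one class's samples by K-SVD.

    The signal matrix ``Y`` has one training vector per column.  Each
    iteration codes ``Y`` with OMP at sparsity ``T0`` against the current
    dictionary, then updates atoms sequentially: for atom ``q`` the residual
    restricted to the signals using ``q`` is formed and its leading singular
    vectors replace the atom and its coefficient row.  Unused atoms are
    re-seeded with the worst-reconstructed signal.  Deterministic given
    ``spec.seed`` (initialization is a random subset of training columns).

    Returns the (dim, atoms_per_class) dictionary, or a tuple
    ``(dictionary, objective)`` with the per-iteration reconstruction error
    ``sum ||y - D x||^2`` when ``return_objective`` is set.
    """
    if isinstance(features_one_class, FeatureMatrix):
        Y = features_one_class.values.T
    else:
        Y = np.asarray(features_one_class, dtype=float)
        if Y.ndim != 2:
            raise ValueError("expected a 2-D signal matrix (dim, n_samples)")
    dim, n = Y.shape
    a = int(spec.atoms_per_class)
    rng = np.random.default_rng(spec.seed)
    init_idx = rng.choice(n, size=a, replace=n < a)
    D = _normalize_columns(Y[:, init_idx].copy())
    objective: list[float] = []
    X_prev: np.ndarray | None = None
    for _ in range(int(spec.iterations)):
        X = _omp_codes(D, Y, spec.sparsity_T0)
        if X_prev is not None:
            # monotone safeguard: greedy OMP has no descent guarantee, so a
            # signal keeps its previous code when the fresh one is worse
            r_new = np.linalg.norm(Y - D @ X, axis=0)
            r_old = np.linalg.norm(Y - D @ X_prev, axis=0)
            worse = r_new > r_old
            X[:, worse] = X_prev[:, worse]
        for q in range(a):
            users = np.flatnonzero(X[q] != 0)
            if users.size == 0:
                # re-seed a dead atom with the currently worst-explained signal
                err = np.linalg.norm(Y - D @ X, axis=0)
                worst = int(np.argmax(err))
                col = Y[:, worst]
                nrm = np.linalg.norm(col)
                if nrm > 0:
                    D[:, q] = col / nrm
                continue
            E = Y[:, users] - D @ X[:, users] + np.outer(D[:, q], X[q, users])
            # rank-1 update: leading singular pair of the restricted residual
            U, S, Vt = np.linalg.svd(E, full_matrices=False)
            D[:, q] = U[:, 0]
            X[q, users] = S[0] * Vt[0]
        objective.append(float(np.sum((Y - D @ X) ** 2)))
        # escape collapsed initializations: an atom nearly colinear with an
        # earlier one hands its coefficients to the twin and is re-seeded
        # with the worst-explained signal
        gram = np.abs(D.T @ D) - np.eye(a)
        err = np.linalg.norm(Y - D @ X, axis=0)
        for q in range(1, a):
            twin = int(np.argmax(gram[q, :q]))
            if gram[q, twin] > 0.99:
                sign = np.sign(D[:, q] @ D[:, twin]) or 1.0
                X[twin] += sign * X[q]
                X[q] = 0.0
                worst = int(np.argmax(err))
                nrm = np.linalg.norm(Y[:, worst])
                if nrm > 0:
                    D[:, q] = Y[:, worst] / nrm
                    err[worst] = 0.0
        X_prev = X
    if return_objective:
        return D, np.asarray(objective)
    return D


def ksvd_learn_per_class(
    features: FeatureMatrix,
    spec: KsvdSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Label-specific learning: run K-SVD per class and concatenate.

    Returns ``(matrix, atom_labels)`` where atoms of each class occupy a
    contiguous column range and carry their class label.
    """
    _require_two_classes(features)
    mats, labels = [], []
    for offset, cls in enumerate(sorted(features.classes_present())):
        sub = features.values[features.labels == cls].T
        D = ksvd_learn(sub, KsvdSpec(spec.atoms_per_class, spec.sparsity_T0,
                                     spec.iterations, spec.seed + offset))
        mats.append(D)
        labels.extend([cls] * D.shape[1])
    return np.hstack(mats), np.asarray(labels, dtype=object)
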