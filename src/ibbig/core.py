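"""Matrix containers and the entropy-based module fitness score.

A *module* (bi-cluster) is a subset ``K`` of the columns (phenotypes) of a
binary gene-set x phenotype association matrix, together with the rows
(gene sets) that support it.  Its fitness is the sum over rows of a
per-row score that rewards rows whose associations concentrate on the
module's columns.

For row ``i`` with weights ``w_ij`` and a module with ``k = |K|`` columns,

    p_i  = (1/k) * sum_{j in K} w_ij              (association probability)
    H_i  = -p log2 p - (1-p) log2 (1-p)           (Shannon entropy, 0 log 0 := 0)
    W_ik = k^alpha * (1 - H_i)^(1-alpha)          (row weight: geometric mean of
                                                   size and homogeneity)
    S_i  = W_ik * sum_{j in K} w_ij               if p_i > 0.5, else 0

The score is asymmetric: rows whose association probability does not
exceed 1/2 contribute nothing, so shared *non*-associations (which can
arise from purely technical causes) are ignored.  ``alpha`` in (0, 1)
balances module size against homogeneity: a larger ``alpha`` both
strengthens the explicit width reward ``k^alpha`` and weakens the
homogeneity penalty ``(1 - H_i)^(1-alpha)``, shifting credit toward
wide, gradient-laden modules (higher sensitivity, lower specificity).

The module score ``S = sum_i S_i`` is what the genetic search maximises;
``log((k/m) * S)`` is the *weighted score* used to rank extracted modules
and to separate genuine modules (positive) from residue and background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AssociationMatrix",
    "WeightMatrix",
    "Module",
    "GAParams",
    "InvalidModuleError",
    "ParameterError",
    "association_probability",
    "entropy",
    "geneset_score",
    "module_score",
    "module_scores_batch",
    "weighted_module_score",
]


class InvalidModuleError(ValueError):
    """Raised for modules with fewer than two columns or bad indices."""


class ParameterError(ValueError):
    """Raised for algorithm parameters outside their documented domain."""


def _check_labels(labels: Sequence[str], n: int, what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError(f"{what}: expected {n} labels, got {len(labels)}")
    if len(set(labels)) != n:
        raise ValueError(f"{what}: labels are not unique")
    return labels


@dataclass
class AssociationMatrix:
    """Binary gene-set x phenotype matrix ``M`` with ``m_ij`` in {0, 1}.

    Rows are gene sets, columns are phenotypes (discretized GSA results:
    one single-sample profile or one pairwise-contrast test per column).
    """

    values: np.ndarray
    row_ids: list[str] = field(default=None)  # type: ignore[assignment]
    col_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        n, m = vals.shape
        if n < 1 or m < 2:
            raise ValueError(f"matrix must be at least 1 x 2, got {n} x {m}")
        uniq = np.unique(vals)
        if not np.isin(uniq, (0, 1)).all():
            bad = uniq[~np.isin(uniq, (0, 1))][0]
            raise ValueError(f"association matrix must be binary; found {bad!r}")
        self.values = vals.astype(np.int8)
        if self.row_ids is None:
            self.row_ids = [f"gs{i}" for i in range(n)]
        if self.col_ids is None:
            self.col_ids = [f"ph{j}" for j in range(m)]
        self.row_ids = _check_labels(self.row_ids, n, "row_ids")
        self.col_ids = _check_labels(self.col_ids, m, "col_ids")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_weights(self) -> "WeightMatrix":
        """Initial weight matrix: identical to ``M`` (iteration 1)."""
        return WeightMatrix(
            values=self.values.astype(np.float64),
            row_ids=list(self.row_ids),
            col_ids=list(self.col_ids),
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    @classmethod
    def from_dataframe(cls, df) -> "AssociationMatrix":
        return cls(values=df.to_numpy(), row_ids=list(df.index), col_ids=list(df.columns))


@dataclass
class WeightMatrix:
    """Real-valued matrix ``W`` of residual signal, same shape/labels as ``M``.

    Entries live in [0, 1] and are entrywise <= the originating binary
    matrix; partial masking after each extracted module reduces them.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2:
            raise ValueError("weight matrix must be 2-D")
        if vals.min(initial=0.0) < -1e-12 or vals.max(initial=0.0) > 1 + 1e-12:
            raise ValueError("weight matrix entries must lie in [0, 1]")
        self.values = np.clip(vals, 0.0, 1.0)
        n, m = vals.shape
        self.row_ids = _check_labels(self.row_ids, n, "row_ids")
        self.col_ids = _check_labels(self.col_ids, m, "col_ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "WeightMatrix":
        return WeightMatrix(self.values.copy(), list(self.row_ids), list(self.col_ids))


@dataclass
class Module:
    """A discovered bi-cluster.

    ``columns`` holds the phenotype indices (the module ``K``),
    ``geneset_scores`` the per-row scores ``S_i`` (importance of each gene
    set to the module), ``geneset_members`` the boolean membership calls,
    ``score`` the total ``S`` and ``weighted_score`` ``log((k/m) S)``.
    ``iteration`` is the 1-based extraction order.
    """

    columns: np.ndarray
    geneset_scores: np.ndarray
    geneset_members: np.ndarray
    score: float
    weighted_score: float = float("-inf")
    iteration: int = 0

    @property
    def k(self) -> int:
        return int(len(self.columns))

    @property
    def n_members(self) -> int:
        return int(np.count_nonzero(self.geneset_members))

    def column_set(self) -> set[int]:
        return set(int(c) for c in self.columns)

    def member_rows(self) -> set[int]:
        return set(np.flatnonzero(self.geneset_members).tolist())


@dataclass(frozen=True)
class GAParams:
    """Genetic-algorithm parameters with their optimised defaults.

    alpha               weighting between homogeneity and module size
    pop_size            population size P
    mutation_rate       probability MR that a child is mutated
    success_ratio       fraction SR of next-generation slots reserved for
                        children that beat at least one parent
    selection_pressure  slope SP of the linear-ranking parent selection
    stagnation          generations without best-fitness improvement
                        before the search stops
    n_modules           modules to extract in an iterative run
    """

    alpha: float = 0.3
    pop_size: int = 100
    mutation_rate: float = 0.08
    success_ratio: float = 0.6
    selection_pressure: float = 1.2
    stagnation: int = 50
    n_modules: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.pop_size < 2:
            raise ParameterError("pop_size must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ParameterError("mutation_rate must be a probability")
        if not 0.0 < self.success_ratio <= 1.0:
            raise ParameterError("success_ratio must be in (0, 1]")
        if not 1.0 <= self.selection_pressure <= 2.0:
            raise ParameterError(
                f"selection_pressure must be in [1, 2], got {self.selection_pressure}"
            )
        if self.stagnation < 1:
            raise ParameterError("stagnation must be a positive integer")
        if self.n_modules < 1:
            raise ParameterError("n_modules must be a positive integer")

    def with_(self, **kwargs) -> "GAParams":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# score primitives
# ---------------------------------------------------------------------------


def _check_module_columns(columns, m: int) -> np.ndarray:
    cols = np.asarray(columns, dtype=np.intp).ravel()
    if cols.size != np.unique(cols).size:
        raise InvalidModuleError("module columns must be distinct")
    if cols.size < 2:
        raise InvalidModuleError(f"a module needs at least 2 columns, got {cols.size}")
    if cols.size and (cols.min() < 0 or cols.max() >= m):
        raise InvalidModuleError("module column index out of range")
    return cols


def association_probability(weight_row: np.ndarray, module_columns) -> float:
    """Fraction (weighted) of the module's phenotypes associated with a row.

    ``p_i = (1/k) sum_{j in K} w_ij``.  On iteration 1 (binary weights)
    this is simply the fraction of module phenotypes the gene set hits.
    """
    row = np.asarray(weight_row, dtype=np.float64).ravel()
    cols = _check_module_columns(module_columns, row.size)
    return float(row[cols].sum() / cols.size)


def entropy(p):
    """Binary Shannon entropy in bits, elementwise, with ``0 log2 0 := 0``.

    ``H(0) = H(1) = 0`` (perfectly homogeneous association or
    non-association); ``H(0.5) = 1`` (random association).
    """
    arr = np.asarray(p, dtype=np.float64)
    if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
        raise ValueError("entropy is defined for p in [0, 1]")
    arr = np.clip(arr, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(arr * np.log2(arr)) - (1.0 - arr) * np.log2(1.0 - arr)
    h = np.where((arr == 0.0) | (arr == 1.0), 0.0, h)
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(h)
    return h


def geneset_score(weight_row: np.ndarray, module_columns, alpha: float) -> float:
    """Score ``S_i`` of one gene set within a module.

    ``S_i = k^alpha * (1 - H_i)^(1 - alpha) * sum_{j in K} w_ij`` when
    the association probability exceeds 1/2, otherwise 0 (asymmetry:
    rows dominated by non-association carry no evidence for the module).
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    row = np.asarray(weight_row, dtype=np.float64).ravel()
    cols = _check_module_columns(module_columns, row.size)
    count = float(row[cols].sum())
    k = cols.size
    p = count / k
    if p <= 0.5:
        return 0.0
    return k**alpha * (1.0 - entropy(p)) ** (1.0 - alpha) * count


def module_score(weights: WeightMatrix | np.ndarray, module_columns, alpha: float):
    """Total module score ``S = sum_i S_i`` and the per-row vector ``S_i``.

    The per-row scores double as the gene-set ranking within the module:
    a large ``S_i`` marks a gene set that is important to the module.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    W = weights.values if isinstance(weights, WeightMatrix) else np.asarray(weights, float)
    cols = _check_module_columns(module_columns, W.shape[1])
    counts = W[:, cols].sum(axis=1)
    p = counts / cols.size
    scores = np.zeros(W.shape[0], dtype=np.float64)
    mask = p > 0.5
    if mask.any():
        scores[mask] = (
            cols.size**alpha * (1.0 - entropy(p[mask])) ** (1.0 - alpha) * counts[mask]
        )
    return float(scores.sum()), scores


def module_scores_batch(W: np.ndarray, membership: np.ndarray, alpha: float) -> np.ndarray:
    """Fitness of many candidate modules at once.

    ``membership`` is a (B, m) 0/1 array of column-membership vectors.
    Individuals with fewer than two columns get fitness 0.  This is the
    hot path of the genetic search; it is a single matrix product.
    """
    B = np.ascontiguousarray(membership, dtype=np.float64)
    k = B.sum(axis=1)
    valid = k >= 2
    counts = B @ W.T  # (B, n): per-row association counts on each candidate
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / k[:, None]
    p = np.nan_to_num(p, nan=0.0)
    gated = p > 0.5
    one_minus_h = np.zeros_like(p)
    pg = p[gated]
    one_minus_h[gated] = (1.0 - entropy(pg)) ** (1.0 - alpha)
    with np.errstate(invalid="ignore"):
        kpow = np.where(valid, k**alpha, 0.0)
    fitness = kpow * (counts * one_minus_h).sum(axis=1)
    fitness[~valid] = 0.0
    return fitness


def weighted_module_score(score: float, k: int, m: int) -> float:
    """Weighted score ``log((k/m) * S)`` (natural log).

    Positive weighted scores mark genuine modules; residue and background
    modules fall at or below zero.  ``S = 0`` maps to ``-inf``.
    """
    if not 2 <= k <= m:
        raise InvalidModuleError(f"module size k={k} outside [2, m={m}]")
    if score < 0:
        raise ValueError("module score must be non-negative")
    if score == 0.0:
        return float("-inf")
    return float(np.log(k / m * score))
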