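"""Functional connectivity network construction.

Per-subject Pearson correlation matrices with Fisher z variance
stabilization, edge-wise one-sample testing with Benjamini-Hochberg FDR
control to retain reliably positive edges, group averaging under a binary
edge mask, proportional (sparsity) thresholding with deterministic
tie-breaking, and connectedness-based sparsity selection over a grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse import csgraph
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConnectivityMatrix",
    "EdgeMask",
    "SparsitySelection",
    "correlation_matrix",
    "edgewise_fdr_mask",
    "group_average",
    "sparsity_threshold",
    "is_connected",
    "select_sparsity",
]


def _check_square_symmetric(values: np.ndarray, tol: float = 1e-12) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(values, values.T, atol=tol, rtol=0.0):
        raise ValueError("matrix must be symmetric")


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N edge-weight matrix with a zero diagonal.

    ``kind`` flags whether entries are raw Pearson r or Fisher z values.
    Node strength ``k_i = sum_j w_ij`` and the ordered-pair total weight
    ``l = sum_ij w_ij`` (twice the unordered edge-weight sum) are derived.
    """

    values: np.ndarray
    labels: list[str] | None = None
    kind: str = "z"  # "r" | "z"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_square_symmetric(self.values)
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        if self.kind == "r" and np.max(np.abs(self.values), initial=0.0) > 1.0:
            raise ValueError("raw correlations must lie in [-1, 1]")
        if self.labels is not None and len(self.labels) != self.n_nodes:
            raise ValueError("label count must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def strength(self) -> np.ndarray:
        return self.values.sum(axis=1)

    @property
    def total_weight(self) -> float:
        return float(self.values.sum())


@dataclass
class EdgeMask:
    """Binary symmetric edge-retention matrix with a provenance tag."""

    values: np.ndarray
    provenance: str = "fdr"  # fdr | sparsity | combined
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        _check_square_symmetric(self.values.astype(float))
        vals = np.unique(self.values)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask entries must be 0/1")
        self.values = self.values.astype(bool)
        np.fill_diagonal(self.values, False)

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.values, 1).sum())

    def __and__(self, other: "EdgeMask") -> "EdgeMask":
        return EdgeMask(self.values & other.values, provenance="combined")


def _as_array(matrix) -> np.ndarray:
    return matrix.values if isinstance(matrix, (ConnectivityMatrix, EdgeMask)) \
        else np.asarray(matrix, dtype=float)


def correlation_matrix(
    ts: np.ndarray,
    fisher: bool = True,
    labels: Sequence[str] | None = None,
) -> ConnectivityMatrix:
    """Pearson correlation of the T x N region series, optionally Fisher
    z-transformed (arctanh, with |r| clamped at 1 - 1e-15), diagonal zeroed.

    Constant regions get all their edges set to 0 with a warning.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("ts must be T x N")
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 timepoints")
    sd = ts.std(axis=0)
    constant = sd == 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(ts, rowvar=False)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant region(s); their edges set to 0",
            stacklevel=2,
        )
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 0.0)
    if fisher:
        corr = np.arctanh(np.clip(corr, -1 + 1e-15, 1 - 1e-15))
        kind = "z"
    else:
        kind = "r"
    return ConnectivityMatrix(corr, labels=list(labels) if labels else None,
                              kind=kind)


def edgewise_fdr_mask(
    zmats: Sequence[np.ndarray | ConnectivityMatrix],
    q: float = 0.05,
    *,
    alternative: str = "greater",
) -> EdgeMask:
    """Edge mask retaining edges whose Fisher-z values are reliably positive
    across subjects.

    For every unordered edge, a one-sample t-test of the subjects' z values
    against zero (one-sided "greater" by default, since the aim is to remove
    weak or negative correlations) is Benjamini-Hochberg corrected over all
    N(N-1)/2 edges at level ``q``; the edge is retained when rejected and the
    group-mean z is positive.  Zero-variance edges degenerate to p = 0 if the
    mean is positive, 1 otherwise (logged).
    """
    arrays = [_as_array(m) for m in zmats]
    if len(arrays) < 3:
        raise ValueError("need at least 3 subjects")
    n = arrays[0].shape[0]
    if any(a.shape != (n, n) for a in arrays):
        raise ValueError("all matrices must share the same size")
    stack = np.stack(arrays)  # S x N x N
    iu = np.triu_indices(n, 1)
    edge_vals = stack[:, iu[0], iu[1]]  # S x E
    s = edge_vals.shape[0]
    mean = edge_vals.mean(axis=0)
    sd = edge_vals.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = mean / (sd / np.sqrt(s))
    if alternative == "greater":
        pvals = stats.t.sf(tstat, df=s - 1)
    elif alternative == "two-sided":
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df=s - 1)
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance edge(s): degenerate p",
            stacklevel=2,
        )
        pvals = np.where(degenerate, np.where(mean > 0, 0.0, 1.0), pvals)
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    keep = reject & (mean > 0)
    mask = np.zeros((n, n), dtype=bool)
    mask[iu[0][keep], iu[1][keep]] = True
    mask |= mask.T
    return EdgeMask(mask, provenance="fdr",
                    detail={"q": q, "pvalues": pvals, "mean_z": mean})


def group_average(
    matrices: Sequence[np.ndarray | ConnectivityMatrix],
    mask: EdgeMask | None = None,
    *,
    kind: str = "z",
) -> ConnectivityMatrix:
    """Elementwise mean of subject matrices with out-of-mask entries zeroed."""
    arrays = [_as_array(m) for m in matrices]
    mean = np.mean(arrays, axis=0)
    if mask is not None:
        if mask.values.shape != mean.shape:
            raise ValueError("mask shape mismatch")
        mean = np.where(mask.values, mean, 0.0)
    np.fill_diagonal(mean, 0.0)
    labels = None
    for m in matrices:
        if isinstance(m, ConnectivityMatrix) and m.labels:
            labels = m.labels
            break
    return ConnectivityMatrix(mean, labels=labels, kind=kind)


def _edge_order(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Upper-triangle edges sorted by decreasing weight, ties by (i, j)."""
    n = values.shape[0]
    iu = np.triu_indices(n, 1)
    w = values[iu]
    order = np.lexsort((iu[1], iu[0], -w))
    n_pos = int((w > 0).sum())
    return iu[0][order], iu[1][order], w[order], n_pos


def sparsity_threshold(
    matrix: np.ndarray | ConnectivityMatrix, sparsity: float
) -> EdgeMask:
    """Retain the ``floor(sparsity * N(N-1)/2)`` largest positive-weight
    unordered edges; ties at the cutoff break toward the lexicographically
    smaller (i, j) node pair."""
    if not 0.0 < sparsity <= 1.0:
        raise ValueError("sparsity must lie in (0, 1]")
    values = _as_array(matrix)
    _check_square_symmetric(values)
    n = values.shape[0]
    budget = int(np.floor(sparsity * n * (n - 1) / 2))
    ii, jj, _, n_pos = _edge_order(values)
    if budget > n_pos:
        warnings.warn(
            f"requested {budget} edges but only {n_pos} have positive weight; "
            "retaining all positive edges",
            stacklevel=2,
        )
        budget = n_pos
    mask = np.zeros((n, n), dtype=bool)
    mask[ii[:budget], jj[:budget]] = True
    mask |= mask.T
    return EdgeMask(mask, provenance="sparsity",
                    detail={"sparsity": sparsity, "n_edges": budget})


def is_connected(mask: EdgeMask | np.ndarray) -> bool:
    """True iff a single graph component spans every node."""
    values = _as_array(mask)
    _check_square_symmetric(values.astype(float))
    graph = sparse.csr_matrix(values != 0)
    n_comp, _ = csgraph.connected_components(graph, directed=False)
    return n_comp == 1


@dataclass
class SparsitySelection:
    sparsity: float
    table: pd.DataFrame  # columns: sparsity, n_connected, selected
    all_connected: bool


def select_sparsity(
    matrices: Sequence[np.ndarray | ConnectivityMatrix],
    lo: float = 0.05,
    hi: float = 0.30,
    step: float = 0.01,
) -> SparsitySelection:
    """Smallest sparsity in the grid at which every subject's thresholded
    network is fully connected.

    If no grid value connects all subjects, the sparsity with maximal
    coverage is reported with ``all_connected=False``.
    """
    if not matrices:
        raise ValueError("need at least one subject matrix")
    grid = np.round(np.arange(lo, hi + step / 2.0, step), 10)
    rows = []
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for s in grid:
            n_conn = sum(
                is_connected(sparsity_threshold(m, float(s))) for m in matrices
            )
            rows.append({"sparsity": float(s), "n_connected": int(n_conn)})
            if best is None and n_conn == len(matrices):
                best = float(s)
    table = pd.DataFrame(rows)
    if best is None:
        fallback = table.loc[table["n_connected"].idxmax(), "sparsity"]
        warnings.warn(
            "no sparsity in the grid yields full connectivity for every "
            f"subject; falling back to max-coverage sparsity {fallback}",
            stacklevel=2,
        )
        best, all_connected = float(fallback), False
    else:
        all_connected = True
    table["selected"] = table["sparsity"] == best
    return SparsitySelection(best, table, all_connected)
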