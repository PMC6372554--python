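"""Weighted-network modularity and greedy modular detection.

The modularity of a partition p of a weighted network is

    Q(p) = (1/l) * sum_ij [ w_ij - k_i k_j / l ] * delta(m_i, m_j)

summed over ordered node pairs (including i = j, with w_ii = 0), where
k_i = sum_j w_ij is the node strength and l = sum_ij w_ij the ordered-pair
total weight.  Under this convention the single-module partition scores
exactly 0 for every graph.

Detection is agglomerative greedy maximization (merge the connected module
pair with the largest modularity gain, keep the best partition along the
path) followed by a local refinement pass that reassigns single nodes to
neighboring modules while that strictly increases Q.  All tie-breaks are by
node/module index, so detection is deterministic without a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph
from scipy.special import comb

from .network import ConnectivityMatrix, EdgeMask, sparsity_threshold

__all__ = [
    "ModularPartition",
    "SparsitySweep",
    "modularity_q",
    "detect_modules",
    "sparsity_sweep",
    "match_partitions",
]

_EPS = 1e-12


@dataclass
class ModularPartition:
    """Node-to-module assignment with its modularity value.

    Module ids are contiguous 0..M-1 in order of first appearance along the
    node index; ``module_names`` optionally attaches domain names.
    """

    module_of: np.ndarray
    q: float
    labels: list[str] | None = None
    module_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.module_of = np.asarray(self.module_of, dtype=np.intp)
        ids = np.unique(self.module_of)
        if not np.array_equal(ids, np.arange(ids.size)):
            raise ValueError("module ids must be contiguous 0..M-1")
        if not np.isfinite(self.q):
            raise ValueError("Q must be finite")

    @property
    def n_modules(self) -> int:
        return int(self.module_of.max()) + 1

    def members(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.module_of == module)

    def to_dict(self) -> dict:
        return {
            "nodes": self.labels,
            "module_of": self.module_of.tolist(),
            "Q": self.q,
            "module_names": self.module_names,
        }


def _weights_array(weights) -> np.ndarray:
    w = weights.values if isinstance(weights, ConnectivityMatrix) \
        else np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be square")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w


def modularity_q(weights, partition) -> float:
    """Modularity Q of ``partition`` on a non-negative weighted network."""
    w = _weights_array(weights)
    if np.any(w < 0):
        raise ValueError("modularity requires non-negative weights")
    assign = partition.module_of if isinstance(partition, ModularPartition) \
        else np.asarray(partition, dtype=np.intp)
    if assign.shape != (w.shape[0],):
        raise ValueError("partition length must match node count")
    l_total = w.sum()
    if w.shape[0] == 0 or l_total <= 0:
        raise ValueError("graph must have positive total weight")
    k = w.sum(axis=1)
    same = assign[:, None] == assign[None, :]
    return float(((w - np.outer(k, k) / l_total) * same).sum() / l_total)


def _canonical(assign: np.ndarray) -> np.ndarray:
    """Relabel module ids contiguously in order of first node occurrence."""
    mapping: dict[int, int] = {}
    out = np.empty_like(assign)
    for i, m in enumerate(assign):
        if m not in mapping:
            mapping[m] = len(mapping)
        out[i] = mapping[m]
    return out


def _greedy_merge(w: np.ndarray) -> np.ndarray:
    """Agglomerative greedy pass; returns the best assignment on the path."""
    n = w.shape[0]
    l_total = w.sum()
    e = w / l_total  # module-pair weight fractions, ordered-pair convention
    a = e.sum(axis=1)
    members: list[list[int]] = [[i] for i in range(n)]
    q = float(np.trace(e) - np.sum(a**2))
    best_q = q
    best = np.arange(n)

    while len(members) > 1:
        m = len(members)
        gain = 2.0 * (e - np.outer(a, a))
        connected = np.triu(e > 0.0, 1)
        if not connected.any():
            break  # remaining modules live in different components
        cand = np.where(connected, gain, -np.inf)
        flat = int(np.argmax(cand))  # row-major: smallest (i, j) among ties
        i, j = divmod(flat, m)
        q += cand[i, j]
        e[i, :] += e[j, :]
        e[:, i] += e[:, j]
        e = np.delete(np.delete(e, j, axis=0), j, axis=1)
        a[i] += a[j]
        a = np.delete(a, j)
        members[i].extend(members[j])
        del members[j]
        if q > best_q + _EPS:
            best_q = q
            best = np.empty(n, dtype=np.intp)
            for mid, nodes in enumerate(members):
                best[nodes] = mid
    return _canonical(best)


def _refine(w: np.ndarray, assign: np.ndarray, max_sweeps: int = 200) -> np.ndarray:
    """Single-node reassignment pass: move a node to a neighboring module
    whenever that strictly increases Q; sweep until no move improves."""
    n = w.shape[0]
    l_total = w.sum()
    k = w.sum(axis=1) / l_total
    assign = assign.copy()
    n_mod = int(assign.max()) + 1
    a_mod = np.bincount(assign, weights=k, minlength=n_mod)
    for _ in range(max_sweeps):
        moved = False
        for v in range(n):
            current = assign[v]
            w_v = np.bincount(assign, weights=w[v], minlength=n_mod) / l_total
            neighbors = np.flatnonzero(w_v > 0.0)
            best_gain, best_mod = _EPS, current
            for b in neighbors:
                if b == current:
                    continue
                gain = 2.0 * (w_v[b] - w_v[current]) \
                    - 2.0 * k[v] * (a_mod[b] - a_mod[current] + k[v])
                if gain > best_gain:
                    best_gain, best_mod = gain, int(b)
            if best_mod != current:
                assign[v] = best_mod
                a_mod[current] -= k[v]
                a_mod[best_mod] += k[v]
                moved = True
        if not moved:
            break
    return _canonical(assign)


def _split_refine(w: np.ndarray, assign: np.ndarray,
                  max_rounds: int = 20) -> np.ndarray:
    """Split pass: re-run greedy detection inside each module's subgraph and
    accept the split when it strictly increases global Q.

    Agglomerative merging can glue two true modules together early, and
    single-node moves cannot undo that; a subgraph-level split can.  Each
    accepted split is followed by a node-level refinement sweep.
    """
    q = modularity_q(w, assign)
    for _ in range(max_rounds):
        improved = False
        for m in range(int(assign.max()) + 1):
            nodes = np.flatnonzero(assign == m)
            if nodes.size < 2:
                continue
            sub = w[np.ix_(nodes, nodes)]
            if sub.sum() <= 0:
                continue
            sub_assign = _refine(sub, _greedy_merge(sub))
            if sub_assign.max() == 0:
                continue  # subgraph does not want to split
            cand = assign.copy()
            base = int(assign.max()) + 1
            moved = sub_assign > 0
            cand[nodes[moved]] = base + sub_assign[moved] - 1
            cand = _canonical(cand)
            q_new = modularity_q(w, cand)
            if q_new > q + _EPS:
                assign, q = cand, q_new
                improved = True
        if not improved:
            break
        assign = _refine(w, assign)
        q = modularity_q(w, assign)
    return _canonical(assign)


def detect_modules(
    weights,
    *,
    refine: bool = True,
    labels: Sequence[str] | None = None,
) -> ModularPartition:
    """Greedy modularity maximization with local refinement.

    Refinement alternates single-node reassignment sweeps with module-level
    split attempts until neither improves Q.  A disconnected input is handled
    per component (greedy merging never crosses components) with a warning.
    """
    w = _weights_array(weights)
    if np.any(w < 0):
        raise ValueError("detection requires non-negative weights")
    if w.sum() <= 0:
        raise ValueError("graph must have positive total weight")
    n_comp, _ = csgraph.connected_components(
        sparse.csr_matrix(w > 0), directed=False
    )
    if n_comp > 1:
        warnings.warn(
            f"input graph has {n_comp} components; modules are detected "
            "within each component",
            stacklevel=2,
        )
    assign = _greedy_merge(w)
    if refine:
        assign = _refine(w, assign)
        assign = _split_refine(w, assign)
    if labels is None and isinstance(weights, ConnectivityMatrix):
        labels = weights.labels
    return ModularPartition(
        module_of=assign,
        q=modularity_q(w, assign),
        labels=list(labels) if labels else None,
    )


@dataclass
class SparsitySweep:
    table: pd.DataFrame  # columns: sparsity, Q, n_modules
    integrated_q: float


def sparsity_sweep(
    matrix,
    lo: float = 0.05,
    hi: float = 0.30,
    step: float = 0.01,
    *,
    refine: bool = True,
) -> SparsitySweep:
    """Maximum modularity and module count across a sparsity grid, plus the
    integrated modularity (trapezoidal mean of Q over the grid span)."""
    grid = np.round(np.arange(lo, hi + step / 2.0, step), 10)
    if grid.size < 2:
        raise ValueError("grid must contain at least two sparsity values")
    rows = []
    w = _weights_array(matrix)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for s in grid:
            mask = sparsity_threshold(w, float(s))
            masked = np.where(mask.values, w, 0.0)
            part = detect_modules(masked, refine=refine)
            rows.append({
                "sparsity": float(s), "Q": part.q, "n_modules": part.n_modules,
            })
    table = pd.DataFrame(rows)
    integrated = float(
        np.trapezoid(table["Q"].to_numpy(), table["sparsity"].to_numpy())
        / (grid[-1] - grid[0])
    )
    return SparsitySweep(table, integrated)


def match_partitions(a, b) -> tuple[np.ndarray, float]:
    """Contingency table and adjusted Rand index of two partitions of the
    same node set (permutation-model chance correction)."""
    assign_a = a.module_of if isinstance(a, ModularPartition) \
        else np.asarray(a, dtype=np.intp)
    assign_b = b.module_of if isinstance(b, ModularPartition) \
        else np.asarray(b, dtype=np.intp)
    if assign_a.shape != assign_b.shape:
        raise ValueError("partitions must cover the same node set")
    n = assign_a.size
    ka = int(assign_a.max()) + 1
    kb = int(assign_b.max()) + 1
    contingency = np.zeros((ka, kb), dtype=np.intp)
    np.add.at(contingency, (assign_a, assign_b), 1)

    sum_comb = comb(contingency, 2).sum()
    sum_a = comb(contingency.sum(axis=1), 2).sum()
    sum_b = comb(contingency.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total if total > 0 else 0.0
    maximum = 0.5 * (sum_a + sum_b)
    if maximum == expected:  # degenerate (e.g. one-vs-all): chance == ceiling
        ari = 1.0 if np.array_equal(_canonical(assign_a),
                                    _canonical(assign_b)) else 0.0
    else:
        ari = float((sum_comb - expected) / (maximum - expected))
    return contingency, ari
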