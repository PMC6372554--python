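"""Intra- and inter-module connectivity under a reference partition.

Intra-module connectivity C_s is the mean weight of the retained edges whose
endpoints both lie in module s; inter-module connectivity C_{s,t} is the mean
weight of the retained edges bridging modules s and t.  Sums run over
unordered edges and the edge counts l_s / l_{s,t} count unordered edges, so
each C is exactly the mean weight of the existing edges.  A module (pair)
with no surviving edges scores 0, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modularity import ModularPartition
from .network import ConnectivityMatrix, EdgeMask

__all__ = [
    "ModuleMetrics",
    "intra_module_connectivity",
    "inter_module_connectivity",
    "subject_module_metrics",
]


def _prep(weights, mask, partition):
    w = weights.values if isinstance(weights, ConnectivityMatrix) \
        else np.asarray(weights, dtype=float)
    assign = partition.module_of if isinstance(partition, ModularPartition) \
        else np.asarray(partition, dtype=np.intp)
    if assign.shape != (w.shape[0],):
        raise ValueError("partition length must match matrix size")
    if mask is None:
        m = w != 0
    else:
        m = mask.values if isinstance(mask, EdgeMask) else np.asarray(mask, bool)
        if m.shape != w.shape:
            raise ValueError("mask shape mismatch")
    m = m.copy()
    np.fill_diagonal(m, False)
    return w, m, assign


def _block_mean(w, m, rows, cols, label: str) -> tuple[float, int]:
    sub_w = w[np.ix_(rows, cols)]
    sub_m = m[np.ix_(rows, cols)]
    l_edges = int(sub_m.sum())
    if l_edges == 0:
        warnings.warn(f"no surviving edges for {label}; C set to 0",
                      stacklevel=3)
        return 0.0, 0
    return float(sub_w[sub_m].sum() / l_edges), l_edges


def intra_module_connectivity(weights, mask, partition, s: int) -> float:
    """Mean weight C_s of the retained edges inside module ``s``."""
    w, m, assign = _prep(weights, mask, partition)
    nodes = np.flatnonzero(assign == s)
    if nodes.size == 0:
        raise ValueError(f"unknown or empty module id {s}")
    sub_w = w[np.ix_(nodes, nodes)]
    sub_m = np.triu(m[np.ix_(nodes, nodes)], 1)
    l_edges = int(sub_m.sum())
    if l_edges == 0:
        warnings.warn(f"no surviving edges within module {s}; C set to 0",
                      stacklevel=2)
        return 0.0
    return float(sub_w[sub_m].sum() / l_edges)


def inter_module_connectivity(weights, mask, partition, s: int, t: int) -> float:
    """Mean weight C_{s,t} of the retained edges bridging modules ``s``,``t``."""
    if s == t:
        raise ValueError("s and t must differ; use intra_module_connectivity")
    w, m, assign = _prep(weights, mask, partition)
    rows = np.flatnonzero(assign == s)
    cols = np.flatnonzero(assign == t)
    if rows.size == 0 or cols.size == 0:
        raise ValueError(f"unknown or empty module id in ({s}, {t})")
    value, _ = _block_mean(w, m, rows, cols, f"module pair ({s}, {t})")
    return value


@dataclass
class ModuleMetrics:
    """All C_s and C_{s,t} values for one subject under a reference partition."""

    subject_id: str
    group: str
    intra: dict[int, float]
    inter: dict[tuple[int, int], float]
    l_intra: dict[int, int]
    l_inter: dict[tuple[int, int], int]
    module_names: list[str] | None = None
    flags: dict = field(default_factory=dict)

    def _mid(self, name_or_id) -> int:
        if isinstance(name_or_id, (int, np.integer)):
            return int(name_or_id)
        if not self.module_names or name_or_id not in self.module_names:
            raise KeyError(f"unknown module name {name_or_id!r}")
        return self.module_names.index(name_or_id)

    def intra_of(self, module) -> float:
        return self.intra[self._mid(module)]

    def inter_of(self, a, b) -> float:
        key = tuple(sorted((self._mid(a), self._mid(b))))
        return self.inter[key]

    def to_frame(self) -> pd.DataFrame:
        def name(mid: int) -> str:
            return self.module_names[mid] if self.module_names else f"M{mid}"

        rows = [
            {"subject_id": self.subject_id, "group": self.group,
             "metric_name": f"intra_{name(s)}", "value": c,
             "l_edges": self.l_intra[s]}
            for s, c in sorted(self.intra.items())
        ] + [
            {"subject_id": self.subject_id, "group": self.group,
             "metric_name": f"inter_{name(s)}_{name(t)}", "value": c,
             "l_edges": self.l_inter[(s, t)]}
            for (s, t), c in sorted(self.inter.items())
        ]
        return pd.DataFrame(rows)


def subject_module_metrics(
    weights,
    partition: ModularPartition,
    mask=None,
    *,
    subject_id: str = "",
    group: str = "",
    module_names: list[str] | None = None,
) -> ModuleMetrics:
    """Every C_s and unordered C_{s,t} for one subject's masked weighted
    matrix under a reference partition."""
    w, m, assign = _prep(weights, mask, partition)
    if isinstance(weights, ConnectivityMatrix) and weights.labels \
            and isinstance(partition, ModularPartition) and partition.labels \
            and weights.labels != partition.labels:
        raise ValueError("matrix and partition node labels disagree")
    n_mod = int(assign.max()) + 1
    if module_names is None and isinstance(partition, ModularPartition):
        module_names = partition.module_names
    intra: dict[int, float] = {}
    l_intra: dict[int, int] = {}
    inter: dict[tuple[int, int], float] = {}
    l_inter: dict[tuple[int, int], int] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for s in range(n_mod):
            nodes = np.flatnonzero(assign == s)
            sub_m = np.triu(m[np.ix_(nodes, nodes)], 1)
            l_edges = int(sub_m.sum())
            l_intra[s] = l_edges
            intra[s] = float(w[np.ix_(nodes, nodes)][sub_m].sum() / l_edges) \
                if l_edges else 0.0
            for t in range(s + 1, n_mod):
                cols = np.flatnonzero(assign == t)
                value, l_st = _block_mean(w, m, nodes, cols, f"({s},{t})")
                inter[(s, t)] = value
                l_inter[(s, t)] = l_st
    return ModuleMetrics(
        subject_id=subject_id, group=group,
        intra=intra, inter=inter, l_intra=l_intra, l_inter=l_inter,
        module_names=list(module_names) if module_names else None,
    )
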