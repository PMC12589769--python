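"""Centrality descriptors of binarized attention graphs.

Every graph snapshot (a directed, unweighted 16-node graph) is summarized by
35 scalars: mean/SD/min/max over nodes of indegree, outdegree, in- and
out-closeness, betweenness, PageRank, hub and authority scores, plus three
global measures (characteristic path length, diameter, global efficiency).

Because PageRank values sum to 1 and hub/authority scores are normalized by
their sums, their means are constant across snapshots; the default retained
set therefore keeps the 19 descriptors that actually vary in time.

All centralities are computed directly on the dense adjacency matrix with
numpy/scipy (shortest paths via ``scipy.sparse.csgraph``, Brandes'
accumulation for betweenness, power iterations for PageRank and HITS): the
graphs are tiny but number in the tens of thousands per recording, so
per-snapshot graph objects are the slow path. SD statistics use the
population convention (divide by N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .errors import DataError, NumericalError

#: Canonical order of the full descriptor battery.
FULL_35 = (
    "mean_indegree", "std_indegree", "min_indegree", "max_indegree",
    "mean_outdegree", "std_outdegree", "min_outdegree", "max_outdegree",
    "mean_incloseness", "std_incloseness", "min_incloseness", "max_incloseness",
    "mean_outcloseness", "std_outcloseness", "min_outcloseness", "max_outcloseness",
    "mean_betweenness", "std_betweenness", "min_betweenness", "max_betweenness",
    "mean_pagerank", "std_pagerank", "min_pagerank", "max_pagerank",
    "mean_hubrank", "std_hubrank", "min_hubrank", "max_hubrank",
    "mean_authrank", "std_authrank", "min_authrank", "max_authrank",
    "cpl", "diameter", "global_efficiency",
)

#: Descriptors with temporal variability, retained by default (19 names).
RETAINED_19 = (
    "diameter", "cpl", "min_incloseness",
    "max_betweenness", "std_betweenness", "mean_betweenness",
    "std_outdegree", "max_indegree", "min_indegree", "std_indegree",
    "max_authrank", "min_authrank", "std_authrank",
    "max_hubrank", "min_hubrank", "std_hubrank",
    "max_pagerank", "min_pagerank", "std_pagerank",
)

METADATA_COLUMNS = ("segment_id", "time_offset", "well_id", "session", "condition")


def _check_adjacency(adjacency: np.ndarray) -> np.ndarray:
    A = np.asarray(adjacency, dtype=bool)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DataError("adjacency must be square")
    if np.any(np.diag(A)):
        raise DataError("adjacency diagonal must be empty (no self-loops)")
    return A


def _stats(values: np.ndarray, prefix: str) -> dict:
    v = np.asarray(values, dtype=np.float64)
    return {
        f"mean_{prefix}": float(v.mean()),
        f"std_{prefix}": float(v.std()),  # population SD
        f"min_{prefix}": float(v.min()),
        f"max_{prefix}": float(v.max()),
    }


def distance_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Directed unweighted all-pairs shortest paths; inf where unreachable."""
    A = _check_adjacency(adjacency)
    return shortest_path(A.astype(np.float64), method="D", directed=True,
                         unweighted=True)


# ---------------------------------------------------------------------------
# node centralities


def degree_stats(adjacency: np.ndarray) -> dict:
    A = _check_adjacency(adjacency)
    indeg = A.sum(axis=0)
    outdeg = A.sum(axis=1)
    return {**_stats(indeg, "indegree"), **_stats(outdeg, "outdegree")}


def closeness_values(adjacency: np.ndarray,
                     D: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """In- and out-closeness per node: reciprocal of the summed geodesic
    distances over reachable counterparts; 0 for a node with none."""
    if D is None:
        D = distance_matrix(adjacency)
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    with np.errstate(invalid="ignore"):
        in_sum = np.where(finite, D, 0.0).sum(axis=0)    # distances j -> i
        out_sum = np.where(finite, D, 0.0).sum(axis=1)   # distances i -> j
    in_close = np.where(in_sum > 0, 1.0 / np.where(in_sum > 0, in_sum, 1.0), 0.0)
    out_close = np.where(out_sum > 0, 1.0 / np.where(out_sum > 0, out_sum, 1.0), 0.0)
    return in_close, out_close


def closeness_stats(adjacency: np.ndarray, D: np.ndarray | None = None) -> dict:
    in_close, out_close = closeness_values(adjacency, D)
    return {**_stats(in_close, "incloseness"), **_stats(out_close, "outcloseness")}


def betweenness_values(adjacency: np.ndarray) -> np.ndarray:
    """Directed betweenness: sum over ordered pairs (j, k), j != i != k, of
    the fraction of shortest j->k paths passing through i (Brandes'
    single-source accumulation, unnormalized)."""
    A = _check_adjacency(adjacency)
    n = A.shape[0]
    succ = [np.flatnonzero(A[v]) for v in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        # BFS from s with path counting
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        order = [s]
        queue = [s]
        while queue:
            nxt = []
            for v in queue:
                for w in succ[v]:
                    if dist[w] < 0:
                        dist[w] = dist[v] + 1
                        nxt.append(w)
                        order.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
            queue = nxt
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc


def betweenness_stats(adjacency: np.ndarray) -> dict:
    return _stats(betweenness_values(adjacency), "betweenness")


def pagerank_values(adjacency: np.ndarray, d: float = 0.85,
                    tol: float = 1e-9, max_iter: int = 1000) -> np.ndarray:
    """PageRank by power iteration with damping d and uniform redistribution
    of dangling-node mass; the node values sum to 1."""
    A = _check_adjacency(adjacency).astype(np.float64)
    n = A.shape[0]
    out = A.sum(axis=1)
    dangling = out == 0
    T = np.zeros_like(A)
    nz = ~dangling
    T[nz] = A[nz] / out[nz, None]
    pr = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        new = (1 - d) / n + d * (T.T @ pr + pr[dangling].sum() / n)
        if np.abs(new - pr).sum() < tol:
            return new / new.sum()
        pr = new
    raise NumericalError("PageRank power iteration did not converge")


def pagerank_stats(adjacency: np.ndarray, d: float = 0.85) -> dict:
    return _stats(pagerank_values(adjacency, d=d), "pagerank")


def hits_values(adjacency: np.ndarray, tol: float = 1e-8,
                max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Hub and authority scores, each normalized to unit sum.

    An edgeless graph has no hub/authority structure: both vectors are all
    zero (flagged by the caller through the zero sum).
    """
    A = _check_adjacency(adjacency).astype(np.float64)
    n = A.shape[0]
    if not A.any():
        return np.zeros(n), np.zeros(n)
    h = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        a = A.T @ h
        a_sum = a.sum()
        if a_sum > 0:
            a /= a_sum
        h_new = A @ a
        h_sum = h_new.sum()
        if h_sum > 0:
            h_new /= h_sum
        if np.abs(h_new - h).sum() < tol:
            h = h_new
            break
        h = h_new
    a = A.T @ h
    if a.sum() > 0:
        a /= a.sum()
    return h, a


def hits_stats(adjacency: np.ndarray) -> dict:
    h, a = hits_values(adjacency)
    return {**_stats(h, "hubrank"), **_stats(a, "authrank")}


# ---------------------------------------------------------------------------
# global descriptors


def global_stats(adjacency: np.ndarray, D: np.ndarray | None = None) -> dict:
    """Characteristic path length, diameter and global efficiency.

    CPL and diameter are computed over the finite ordered-pair distances
    (unreachable pairs excluded); when no pair is connected they are coded
    NaN. Global efficiency averages 1/distance over all N(N-1) ordered pairs
    with 1/inf = 0, so an empty graph scores 0.
    """
    if D is None:
        D = distance_matrix(adjacency)
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    n_pairs = n * (n - 1)
    if finite.any():
        dists = D[finite]
        cpl = float(dists.mean())
        diameter = float(dists.max())
        glob_eff = float(np.sum(1.0 / dists) / n_pairs)
    else:
        cpl = float("nan")
        diameter = float("nan")
        glob_eff = 0.0
    return {"cpl": cpl, "diameter": diameter, "global_efficiency": glob_eff}


# ---------------------------------------------------------------------------
# assembly


def descriptor_vector(adjacency: np.ndarray) -> dict:
    """The full 35-descriptor summary of one graph snapshot."""
    A = _check_adjacency(adjacency)
    D = distance_matrix(A)
    out: dict = {}
    out.update(degree_stats(A))
    out.update(closeness_stats(A, D))
    out.update(betweenness_stats(A))
    out.update(pagerank_stats(A))
    out.update(hits_stats(A))
    out.update(global_stats(A, D))
    return {name: out[name] for name in FULL_35}


@dataclass
class DescriptorTimeSeries:
    """Descriptor values per graph snapshot, as a tidy table.

    ``table`` has one row per snapshot with the 35 descriptor columns plus
    segment_id and time_offset (1..L-T); well/session/condition metadata are
    attached when known.
    """

    table: pd.DataFrame
    retained_names: tuple = RETAINED_19

    @property
    def retained(self) -> pd.DataFrame:
        meta = [c for c in METADATA_COLUMNS if c in self.table.columns]
        return self.table[list(self.retained_names) + meta]

    @property
    def full(self) -> pd.DataFrame:
        return self.table

    def to_csv(self, path, retained_only: bool = False) -> None:
        (self.retained if retained_only else self.table).to_csv(path, index=False)


def descriptor_timeseries(snapshots: list, well_id: str | None = None,
                          session: str | None = None,
                          condition: str | None = None) -> DescriptorTimeSeries:
    """Compute the full descriptor battery for a snapshot sequence."""
    if not snapshots:
        raise DataError("empty snapshot sequence")
    rows = []
    for snap in snapshots:
        row = descriptor_vector(snap.adjacency)
        row["segment_id"] = snap.segment_id
        row["time_offset"] = snap.time_index
        rows.append(row)
    table = pd.DataFrame(rows)
    if well_id is not None:
        table["well_id"] = well_id
    if session is not None:
        table["session"] = session
    if condition is not None:
        table["condition"] = condition
    return DescriptorTimeSeries(table=table)
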