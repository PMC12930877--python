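"""Hierarchical Ward clustering of discordant phenotypes, from scratch.

The agglomeration minimizes the increase in total within-cluster sum of
squares (Ward's objective) over Euclidean space.  Inter-cluster distances
are maintained with the Lance-Williams recurrence on squared distances,

    D2(u+v, k) = [(n_u + n_k) D2(u,k) + (n_v + n_k) D2(v,k) - n_k D2(u,v)]
                 / (n_u + n_v + n_k),

initialized with squared Euclidean distances between rows, so that
``D2(A, B) = 2 * dESS(A, B)`` where dESS is the ESS increase caused by the
merge.  Reported merge heights are ``sqrt(D2)`` — the Euclidean-scale
("ward.D2"-style) convention, in which the height of merging two singletons
equals their Euclidean distance.  Ties in the minimum-merge selection break
on the lowest (left-id, right-id) pair, making trees deterministic and
independent of row permutations up to leaf ids.

Node numbering follows the usual convention: leaves are ``0 .. n-1``; the
i-th merge creates node ``n + i``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

_TIE_REL_TOL = 1e-9


@dataclass(frozen=True)
class Merge:
    left: int
    right: int
    height: float
    size: int


@dataclass(frozen=True)
class LinkageTree:
    merges: tuple[Merge, ...]
    n_leaves: int

    def __post_init__(self) -> None:
        if self.merges and self.merges[-1].size != self.n_leaves:
            raise ValueError("final merge must contain every leaf")

    def to_array(self) -> np.ndarray:
        """(n-1, 4) linkage array: left, right, height, size."""
        return np.array([[m.left, m.right, m.height, m.size] for m in self.merges],
                        dtype=float)


@dataclass(frozen=True)
class ClusterSolution:
    k: int
    labels: np.ndarray          # per-row labels 1..k, ordered by descending size
    ids: tuple[str, ...]        # row identifiers (case ids)
    sizes: tuple[int, ...]

    @property
    def assignments(self) -> dict:
        return dict(zip(self.ids, self.labels.tolist()))


def ward_linkage(X: Sequence[Sequence[float]]) -> LinkageTree:
    """Agglomerative Ward tree of the rows of ``X`` (binary or numeric)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (rows = observations)")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to cluster")

    # squared Euclidean distances, kept in a dict keyed by active node ids
    diff = X[:, None, :] - X[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d2[i, j])
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    active = set(range(n))

    merges: list[Merge] = []
    next_id = n
    last_height = 0.0
    for _ in range(n - 1):
        # minimum Ward distance with deterministic tie-breaking
        best = min(dist[key] for key in dist)
        tol = _TIE_REL_TOL * max(1.0, abs(best))
        i, j = min(key for key, v in dist.items() if v <= best + tol)
        d_merge = dist[(i, j)]
        height = float(np.sqrt(max(d_merge, 0.0)))
        if height < last_height - 1e-9:
            raise AssertionError("Ward merge heights must be non-decreasing")
        last_height = max(last_height, height)

        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k_ in list(active):
            if k_ in (i, j):
                continue
            nk = sizes[k_]
            dik = dist[tuple(sorted((i, k_)))]
            djk = dist[tuple(sorted((j, k_)))]
            dnew = ((ni + nk) * dik + (nj + nk) * djk - nk * d_merge) / (ni + nj + nk)
            dist[tuple(sorted((new, k_)))] = dnew
        # drop rows/cols of i and j
        for key in [key for key in dist if i in key or j in key]:
            del dist[key]
        active.discard(i)
        active.discard(j)
        active.add(new)
        sizes[new] = ni + nj
        merges.append(Merge(left=i, right=j, height=height, size=ni + nj))
    return LinkageTree(merges=tuple(merges), n_leaves=n)


def cut_tree(tree: LinkageTree, k: int,
             ids: Optional[Sequence[str]] = None) -> ClusterSolution:
    """Cut into ``k`` clusters by undoing the k-1 highest (= last) merges.

    Labels are renumbered 1..k by descending cluster size (ties: cluster
    containing the lowest leaf index first).
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(n + len(tree.merges)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for idx, m in enumerate(tree.merges[: n - k]):
        node = n + idx
        parent[find(m.left)] = node
        parent[find(m.right)] = node

    roots = [find(i) for i in range(n)]
    members: dict[int, list[int]] = {}
    for leaf, root in enumerate(roots):
        members.setdefault(root, []).append(leaf)
    ordered = sorted(members.values(), key=lambda ms: (-len(ms), min(ms)))
    labels = np.zeros(n, dtype=int)
    for label, ms in enumerate(ordered, start=1):
        labels[ms] = label
    if ids is None:
        ids = tuple(str(i) for i in range(n))
    return ClusterSolution(k=k, labels=labels, ids=tuple(ids),
                           sizes=tuple(len(ms) for ms in ordered))


def select_discordant(class_bool: pd.DataFrame,
                      reference: Sequence[bool],
                      cohort) -> tuple[list[str], pd.DataFrame]:
    """Reference-positive cases not classified by at least one system.

    Returns the discordant case ids and their binary feature matrix
    (present = 1, absent/unknown = 0).
    """
    ref = np.asarray(reference, dtype=bool)
    case_ids = [pid for pid, r in zip(class_bool.index, ref) if r]
    case_df = class_bool.loc[case_ids]
    discordant = [pid for pid in case_ids if not case_df.loc[pid].all()]
    fm = cohort.feature_matrix()
    return discordant, fm.loc[discordant]


def characterize(solution: ClusterSolution, features: pd.DataFrame,
                 class_bool: pd.DataFrame) -> dict:
    """Per-cluster feature prevalence and per-system miss patterns.

    Returns ``feature_prevalence`` (cluster x feature, percent),
    ``miss_counts`` / ``miss_rates`` (cluster x system; a discordant case is
    "missed" by the systems that did not classify it), ``sizes``, and
    ``system_order`` (systems sorted by ascending total miss rate, so the
    best-performing system comes first).
    """
    ids = list(solution.ids)
    feats = features.loc[ids]
    missed = ~class_bool.loc[ids]
    labels = pd.Series(solution.labels, index=ids, name="cluster")
    prevalence = feats.groupby(labels).mean() * 100.0
    miss_counts = missed.groupby(labels).sum().astype(int)
    sizes = pd.Series(solution.sizes, index=range(1, solution.k + 1), name="size")
    miss_rates = miss_counts.div(sizes, axis=0) * 100.0
    totals = missed.sum().astype(int)
    system_order = list(totals.sort_values(kind="mergesort").index)
    return {"feature_prevalence": prevalence, "miss_counts": miss_counts,
            "miss_rates": miss_rates, "sizes": sizes,
            "total_misses": totals, "system_order": system_order}


def to_newick(tree: LinkageTree, leaf_names: Optional[Sequence[str]] = None) -> str:
    """Dendrogram as a Newick string with branch lengths derived from merge heights."""
    n = tree.n_leaves
    names = list(leaf_names) if leaf_names is not None else [str(i) for i in range(n)]
    height: dict[int, float] = {i: 0.0 for i in range(n)}
    text: dict[int, str] = {i: names[i] for i in range(n)}
    for idx, m in enumerate(tree.merges):
        node = n + idx
        bl = m.height - height[m.left], m.height - height[m.right]
        text[node] = f"({text[m.left]}:{max(bl[0], 0.0):.6g},{text[m.right]}:{max(bl[1], 0.0):.6g})"
        height[node] = m.height
    return text[n + len(tree.merges) - 1] + ";"
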