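"""Ward agglomerative clustering and locus-bootstrap bipartition support.

The clustering is the Lance–Williams recurrence with Ward coefficients.
Two conventions are offered: the default ``"d2"`` squares the input
distances before the recurrence and reports heights on the original scale
(square root of the merge criterion) — the convention under which the
recurrence minimizes the Ward variance objective for Euclidean-embeddable
distances; ``"d"`` applies the recurrence to the raw distances.  Ties are
broken by the lexicographically smallest pair of cluster indices (leaves
0..n−1, then new clusters n, n+1, ... in merge order).

Branch confidence comes from resampling loci with replacement: each
replicate panel is re-distanced and re-clustered, and each internal
bipartition of the original tree is scored by the percentage of replicate
trees containing it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import DistanceMatrix, psa_distance
from .panel import GenotypePanel


@dataclass
class Dendrogram:
    """Binary merge tree over samples.

    `merges[r]` holds the two node ids joined at step r (leaves are
    0..n−1; the new cluster from step r has id n+r), `heights[r]` the
    merge height (nondecreasing).  `support` — when present — holds, per
    merge node, the bootstrap percentage of its bipartition; the root's
    entry is NaN (its bipartition is trivial).
    """

    leaf_names: list[str]
    merges: np.ndarray
    heights: np.ndarray
    support: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.leaf_names)
        self.merges = np.asarray(self.merges, dtype=int)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.merges.shape != (n - 1, 2):
            raise ValueError("a binary tree over n leaves has n-1 merges")
        if np.any(np.diff(self.heights) < -1e-9):
            raise ValueError("merge heights must be nondecreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def clusters(self) -> list[frozenset[int]]:
        """Leaf-index set of every node, leaves first then merge nodes."""
        n = self.n_leaves
        out: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
        for a, b in self.merges:
            out.append(out[a] | out[b])
        return out

    def bipartitions(self) -> dict[int, frozenset[int]]:
        """Non-trivial bipartition key per internal node id (root excluded).

        The key is the side of the split not containing leaf 0, so equal
        splits compare equal regardless of orientation.
        """
        n = self.n_leaves
        clusters = self.clusters()
        full = frozenset(range(n))
        out = {}
        for r in range(n - 2):  # last merge (root) excluded
            c = clusters[n + r]
            out[n + r] = c if 0 not in c else full - c
        return out

    def cut(self, k: int) -> np.ndarray:
        """Labels (0..k-1) from cutting the tree into k clusters."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError("k must lie in 1..n_leaves")
        n = self.n_leaves
        parent = list(range(2 * n - 1))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for r in range(n - k):
            a, b = self.merges[r]
            new = n + r
            parent[find(a)] = new
            parent[find(b)] = new
        roots = {}
        labels = np.empty(n, dtype=int)
        for i in range(n):
            root = find(i)
            labels[i] = roots.setdefault(root, len(roots))
        return labels

    # ------------------------------------------------------------------ newick
    def to_newick(self, decimals: int = 6, min_support_label: float | None = None) -> str:
        """Newick string; internal-node labels carry bootstrap support.

        Branch lengths are height differences between a node and its
        parent.  With `min_support_label`, only supports at or above the
        threshold are written (mirroring dendrogram figures that label
        confident branches only).
        """
        n = self.n_leaves
        node_h = np.concatenate([np.zeros(n), self.heights])

        def render(node: int, parent_h: float) -> str:
            bl = f":{parent_h - node_h[node]:.{decimals}f}"
            if node < n:
                return f"{self.leaf_names[node]}{bl}"
            a, b = self.merges[node - n]
            inner = f"({render(a, node_h[node])},{render(b, node_h[node])})"
            label = ""
            if self.support is not None and node - n < len(self.support):
                s = self.support[node - n]
                if np.isfinite(s) and (min_support_label is None or s >= min_support_label):
                    label = f"{s:g}"
            return f"{inner}{label}{bl}"

        root = 2 * n - 2
        a, b = self.merges[-1]
        h = node_h[root]
        return f"({render(a, h)},{render(b, h)});"


def write_newick(dendrogram: Dendrogram, path, **kwargs) -> None:
    """Write the tree to `path` in Newick format (see :meth:`to_newick`)."""
    with open(path, "w") as fh:
        fh.write(dendrogram.to_newick(**kwargs) + "\n")


def ward_cluster(dm: DistanceMatrix, variant: str = "d2") -> Dendrogram:
    """Agglomerate a distance matrix by Ward's criterion.

    variant "d2" (default): Lance–Williams on squared distances, heights
    reported as the square root of the criterion (original distance
    scale).  variant "d": the recurrence on raw distances.
    """
    if variant not in ("d", "d2"):
        raise ValueError("variant must be 'd' or 'd2'")
    n = dm.n
    if n < 2:
        raise ValueError("need at least 2 samples")
    work = dm.D.astype(float) ** 2 if variant == "d2" else dm.D.astype(float)
    np.fill_diagonal(work, np.inf)
    size = np.ones(n)
    cluster_id = np.arange(n)  # id of the cluster occupying each slot
    active = np.ones(n, dtype=bool)
    merges = np.empty((n - 1, 2), dtype=int)
    heights = np.empty(n - 1)

    for step in range(n - 1):
        sub = work[np.ix_(active, active)]
        dmin = sub.min()
        # ties: smallest (min id, max id) pair
        idx_active = np.flatnonzero(active)
        best = None
        ii, jj = np.nonzero(np.isclose(sub, dmin, rtol=0, atol=1e-12))
        for a, b in zip(ii, jj):
            if a >= b:
                continue
            sa, sb = idx_active[a], idx_active[b]
            ca, cb = cluster_id[sa], cluster_id[sb]
            key = (min(ca, cb), max(ca, cb))
            if best is None or key < best[0]:
                best = (key, sa, sb)
        _, si, sj = best
        merges[step] = sorted((cluster_id[si], cluster_id[sj]))
        heights[step] = np.sqrt(max(work[si, sj], 0.0)) if variant == "d2" else work[si, sj]

        # Lance-Williams update for Ward's criterion; new cluster in slot si
        ni, nj = size[si], size[sj]
        for sk in np.flatnonzero(active):
            if sk == si or sk == sj:
                continue
            nk = size[sk]
            d_new = (
                (ni + nk) * work[si, sk] + (nj + nk) * work[sj, sk] - nk * work[si, sj]
            ) / (ni + nj + nk)
            work[si, sk] = d_new
            work[sk, si] = d_new
        size[si] = ni + nj
        active[sj] = False
        cluster_id[si] = n + step
    return Dendrogram(list(dm.sample_ids), merges, heights)


def bootstrap_support(
    panel: GenotypePanel,
    n_boot: int = 1000,
    seed: int = 0,
    variant: str = "d2",
) -> Dendrogram:
    """Locus-bootstrap support for the Ward tree of a panel.

    Loci are resampled with replacement (L out of L) `n_boot` times; each
    replicate is re-distanced (1−PSA) and re-clustered, and each internal
    bipartition of the original tree is scored by the percentage of
    replicate trees that contain it.  The original topology is returned
    with its `support` filled (root entry NaN).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    tree = ward_cluster(psa_distance(panel), variant=variant)
    n = panel.n_samples
    orig = tree.bipartitions()
    counts = {node: 0 for node in orig}
    rng = np.random.default_rng(seed)
    L = panel.n_loci
    for _ in range(n_boot):
        idx = rng.integers(0, L, size=L)
        rep_panel = GenotypePanel(
            panel.sample_ids,
            [f"b{j}" for j in range(L)],
            panel.calls[:, idx].copy(),
        )
        rep_tree = ward_cluster(psa_distance(rep_panel), variant=variant)
        rep_bips = set(rep_tree.bipartitions().values())
        for node, bip in orig.items():
            if bip in rep_bips:
                counts[node] += 1
    support = np.full(n - 1, np.nan)
    for node, c in counts.items():
        support[node - n] = 100.0 * c / n_boot
    tree.support = support
    return tree
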