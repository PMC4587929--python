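"""Neighbor-joining trees from K2P matrices, with bootstrap support.

Saitou & Nei agglomeration on the Q-criterion, with two documented
conventions: ties in the Q matrix are broken toward the lowest index
pair (deterministic across runs), and negative branch lengths are
clamped to zero by default (with a counter, so the event is visible).
The unrooted tree is represented with a trifurcating root, as usual for
distance trees.

Bootstrap support resamples alignment columns with replacement,
recomputes the K2P matrix and NJ topology per replicate, and reports the
percentage of replicates containing each internal bipartition of the
full-data tree. A single master seed drives per-replicate child streams,
so results are reproducible and independent of specimen input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .distance import DEFAULT_MIN_OVERLAP, DistanceMatrix, encode_sequences
from .library import BarcodeLibrary


@dataclass
class SupportedTree:
    """An unrooted NJ tree plus bootstrap bookkeeping."""

    tree: TreeNode
    n_clamped_branches: int = 0
    replicates: int = 0
    n_dropped_replicates: int = 0

    def newick(self) -> str:
        return str(self.tree).strip()

    def tip_names(self) -> set[str]:
        return {t.name for t in self.tree.tips()}


def nj_tree(
    dm: DistanceMatrix, allow_negative: bool = False
) -> SupportedTree:
    """Neighbor-joining tree from a complete distance matrix.

    Raises if any pairwise distance is undefined (NJ needs a complete
    matrix) or fewer than 3 specimens are present.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("NJ needs at least 3 specimens")
    iu, ju = np.triu_indices(n, 1)
    if np.isnan(dm.d[iu, ju]).any():
        bad = int(np.isnan(dm.d[iu, ju]).sum())
        raise ValueError(f"NJ needs a complete matrix; {bad} undefined pair(s)")

    D = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.ids]
    active = list(range(n))
    clamped = 0

    def fix(x: float) -> float:
        nonlocal clamped
        if x < 0 and not allow_negative:
            clamped += 1
            return 0.0
        return float(x)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), m)  # row-major argmin = lowest-index tie-break
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        left, right = nodes[active[i]], nodes[active[j]]
        left.length = fix(li)
        right.length = fix(lj)
        parent = TreeNode(children=[left, right])
        # distances from the new node to every other active node
        ai, aj = active[i], active[j]
        new_d = 0.5 * (D[ai, :] + D[aj, :] - dij)
        D[ai, :] = new_d
        D[:, ai] = new_d
        D[ai, ai] = 0.0
        nodes[ai] = parent
        active.pop(j)

    # resolve the final three nodes around a trifurcating root
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        nodes[idx].length = fix(ln)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return SupportedTree(tree=root, n_clamped_branches=clamped)


def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial splits of the taxon set, canonicalized.

    Each internal edge splits the taxa in two; the side *not* containing
    the lexicographically smallest taxon is stored, so splits compare
    across differently rooted representations.
    """
    ref = min(taxa)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        canon = side if ref not in side else taxa - side
        splits.add(frozenset(canon))
    return splits


def _k2p_matrix_from_encoded(X: np.ndarray, min_overlap: int) -> np.ndarray:
    n = X.shape[0]
    d = np.zeros((n, n))
    present = X >= 0
    parity = X & 1
    for i in range(n - 1):
        valid = present[i] & present[i + 1 :]
        diff = valid & (X[i] != X[i + 1 :])
        ts = (diff & (parity[i] == parity[i + 1 :])).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        L = valid.sum(axis=1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = ts / L
            Q = tv / L
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            row = np.where((w1 > 0) & (w2 > 0), -0.5 * np.log(w1 * np.sqrt(np.abs(w2))), np.nan)
        row[L < min_overlap] = np.nan
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return d


def bootstrap_support(
    library: BarcodeLibrary,
    replicates: int = 1000,
    seed: int | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    allow_negative: bool = False,
) -> SupportedTree:
    """Full-data NJ tree with per-edge bootstrap support percentages.

    Alignment columns are resampled with replacement per replicate;
    replicates whose resampled K2P matrix contains an undefined pair are
    dropped and counted. Support values are attached to the internal
    nodes of the full-data tree (``node.support``, also used as the
    newick internal label).
    """
    library.require_aligned("bootstrap resampling")
    from .distance import pairwise_matrix  # local import to avoid cycle at module load

    # canonical specimen order (sorted IDs) for both the full-data tree and
    # the resampling streams, so results do not depend on input order
    lib_sorted = BarcodeLibrary(
        tuple(sorted(library.records, key=lambda r: r.specimen_id))
    )
    full_dm = pairwise_matrix(lib_sorted, min_overlap=min_overlap)
    result = nj_tree(full_dm, allow_negative=allow_negative)
    taxa = frozenset(library.ids)
    target_splits = _bipartitions(result.tree, taxa)
    counts = {s: 0 for s in target_splits}

    X = encode_sequences(r.sequence for r in lib_sorted)
    names = list(lib_sorted.ids)
    L = X.shape[1]
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(replicates)
    dropped = 0
    used = 0
    for cs in child_seeds:
        rng = np.random.default_rng(cs)
        cols = rng.integers(0, L, size=L)
        d = _k2p_matrix_from_encoded(X[:, cols], min_overlap)
        iu, ju = np.triu_indices(len(names), 1)
        if np.isnan(d[iu, ju]).any():
            dropped += 1
            continue
        rep_dm = DistanceMatrix(ids=tuple(names), d=d, sites=np.zeros_like(d, dtype=np.int32))
        rep_tree = nj_tree(rep_dm, allow_negative=allow_negative)
        rep_splits = _bipartitions(rep_tree.tree, taxa)
        used += 1
        for s in target_splits & rep_splits:
            counts[s] += 1

    if used == 0:
        raise ValueError("every bootstrap replicate was dropped (undefined distances)")
    support = {s: 100.0 * c / used for s, c in counts.items()}
    ref = min(taxa)
    for node in result.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        canon = side if ref not in side else taxa - side
        val = support.get(frozenset(canon))
        if val is not None:
            node.support = val
            node.name = f"{val:.0f}"
    result.replicates = replicates
    result.n_dropped_replicates = dropped
    return result


def species_monophyly(
    stree: SupportedTree, library: BarcodeLibrary
) -> dict[str, bool]:
    """Per-species monophyly on an unrooted tree.

    A species with >= 2 specimens is monophyletic iff some edge
    bipartition isolates exactly its specimens (either side of the
    split); singletons are trivially monophyletic.
    """
    taxa = frozenset(library.ids)
    if stree.tip_names() != taxa:
        raise ValueError("tree tips do not match library specimens")
    splits = set()
    for node in stree.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        splits.add(side)
        splits.add(taxa - side)
    # tip edges also define (singleton, rest) splits
    for t in stree.tree.tips():
        splits.add(frozenset([t.name]))

    out = {}
    for sp, idx in library.species_index().items():
        members = frozenset(library.ids[i] for i in idx)
        out[sp] = len(members) == 1 or members in splits or members == taxa
    return out


def write_newick(stree: SupportedTree, sink) -> None:
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            stree.tree.write(fh)
    else:
        stree.tree.write(sink)


def read_newick(source) -> SupportedTree:
    tree = TreeNode.read(source)
    return SupportedTree(tree=tree)
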