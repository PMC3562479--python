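"""Clustering of interface distances and sequence-position discovery.

The VH–VL packing modes are found by hierarchical clustering of the
``1 - GDT_HA`` distance matrix over the 20 canonical interface positions.
Both divisive (DIANA) and agglomerative (average / complete / ward /
single linkage) hierarchies are built, flat partitions are scored with the
mean silhouette width, and the method x k combination with the highest
silhouette is selected.  Sequence positions that discriminate the modes
are ranked by mean Gini impurity decrease in a random-forest classifier
trained on one-hot encoded Kabat–Chothia positions; the resulting
single-residue rule (proline at L44 -> type A) and the nearest-centroid
structural classifier are both provided.

DIANA is implemented here (no maintained Python implementation exists);
linkage algebra is delegated to scipy and the silhouette to scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import silhouette_samples

from .model import (
    GAP,
    FvError,
    FvStructure,
    InterfaceSelection,
    NumberedSequence,
    PositionId,
    extract_interface,
)
from .geometry import interface_distance

L44 = PositionId.parse("L44")

AGGLOMERATIVE_LINKAGES = ("average", "complete", "ward", "single")


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise FvError("distance matrix shape does not match ids")
        if np.any(v < 0) or np.max(np.abs(np.diag(v))) > 1e-12:
            raise FvError("distances must be >= 0 with zero diagonal")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise FvError("distance matrix must be symmetric")
        self.values = v

    def __len__(self) -> int:
        return len(self.ids)


# A dendrogram node is either a leaf index (int) or (left, right, height).
Tree = object


@dataclass
class ClusteringResult:
    method: str
    ids: list[str]
    tree: Tree
    labels_by_k: dict[int, np.ndarray]
    silhouette_by_k: dict[int, float]
    chosen_k: Optional[int] = None
    degenerate: bool = False

    @property
    def labels(self) -> np.ndarray:
        if self.chosen_k is None:
            return np.zeros(len(self.ids), dtype=int)
        return self.labels_by_k[self.chosen_k]

    @property
    def silhouette(self) -> float:
        if self.chosen_k is None:
            return float("nan")
        return self.silhouette_by_k[self.chosen_k]

    def to_newick(self) -> str:
        def render(node) -> str:
            if isinstance(node, (int, np.integer)):
                return self.ids[int(node)]
            left, right, height = node
            return f"({render(left)},{render(right)}):{height:.6g}"

        return render(self.tree) + ";" if not isinstance(self.tree, (int, np.integer)) else f"({self.ids[int(self.tree)]});"


def build_distance_matrix(
    structures: Sequence[FvStructure],
    max_missing: int = 2,
    distance_fn: Callable[[InterfaceSelection, InterfaceSelection], float] = interface_distance,
) -> DistanceMatrix:
    """Pairwise ``1 - GDT_HA`` matrix over structures (computed once per pair)."""
    if len(structures) < 2:
        raise FvError("need at least 2 structures")
    sels = []
    for s in structures:
        try:
            sels.append(extract_interface(s, max_missing=max_missing))
        except FvError as e:
            raise FvError(f"{s.id}: {e}") from e
    n = len(sels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = distance_fn(sels[i], sels[j])
            except FvError as e:
                raise FvError(f"({sels[i].structure_id}, {sels[j].structure_id}): {e}") from e
            values[i, j] = values[j, i] = d
    return DistanceMatrix([s.id for s in structures], values)


# ---------------------------------------------------------------------------
# DIANA


def _diana_split(d: np.ndarray, members: list[int]) -> tuple[list[int], list[int]]:
    """One divisive step: split ``members`` into (splinter, remainder).

    The splinter is seeded by the member with the largest average
    dissimilarity to the rest; members then defect to the splinter while
    their average dissimilarity to the remainder exceeds that to the
    splinter.  Ties are broken by lowest index.
    """
    sub = d[np.ix_(members, members)]
    m = len(members)
    avg = sub.sum(axis=1) / (m - 1)
    seed = int(np.argmax(avg))  # argmax takes the first (lowest index) on ties
    splinter = [seed]
    remainder = [i for i in range(m) if i != seed]
    while len(remainder) > 1:
        best_gain, best_j = 0.0, None
        for j in remainder:
            others = [r for r in remainder if r != j]
            gain = sub[j, others].mean() - sub[j, splinter].mean()
            if gain > best_gain:
                best_gain, best_j = gain, j
        if best_j is None:
            break
        splinter.append(best_j)
        remainder.remove(best_j)
    return [members[i] for i in splinter], [members[i] for i in remainder]


def diana_cluster(m: DistanceMatrix, k_range: Iterable[int] = range(2, 11)) -> ClusteringResult:
    """Classical DIANA divisive hierarchy over a distance matrix.

    At each stage the cluster with the largest diameter is split; the
    height recorded for a split is that diameter.  Flat ``k``-cluster
    labels are the partition after ``k - 1`` splits.
    """
    d = m.values
    n = len(m)
    if n < 2:
        raise FvError("need at least 2 objects")

    clusters: list[list[int]] = [list(range(n))]
    partitions: dict[int, list[list[int]]] = {}

    def diameter(c: list[int]) -> float:
        if len(c) < 2:
            return 0.0
        return float(d[np.ix_(c, c)].max())

    split_children: dict[tuple[int, ...], tuple[list[int], list[int], float]] = {}
    while True:
        diams = [diameter(c) for c in clusters]
        order = sorted(range(len(clusters)), key=lambda i: (-diams[i], min(clusters[i])))
        target = next((i for i in order if diams[i] > 0 and len(clusters[i]) > 1), None)
        if target is None:
            break
        c = clusters.pop(target)
        sp, rem = _diana_split(d, c)
        split_children[tuple(sorted(c))] = (sp, rem, diams[target])
        clusters.extend([sp, rem])
        partitions[len(clusters)] = [list(c) for c in clusters]

    def build(members: list[int]) -> Tree:
        if len(members) == 1:
            return members[0]
        key = tuple(sorted(members))
        if key in split_children:
            sp, rem, h = split_children[key]
            return (build(sp), build(rem), h)
        # unsplit multi-member cluster (zero diameter): left-comb at height 0
        node: Tree = members[0]
        for x in members[1:]:
            node = (node, x, 0.0)
        return node

    tree = build(list(range(n)))

    labels_by_k: dict[int, np.ndarray] = {}
    sil_by_k: dict[int, float] = {}
    for k in k_range:
        if k not in partitions:
            continue
        labels = np.zeros(n, dtype=int)
        for lab, c in enumerate(partitions[k]):
            labels[c] = lab
        labels_by_k[k] = labels
        sil_by_k[k] = silhouette(m, labels)
    result = ClusteringResult("diana", list(m.ids), tree, labels_by_k, sil_by_k)
    _choose_k(result)
    return result


# ---------------------------------------------------------------------------
# Agglomerative (scipy)


def _linkage_to_tree(Z: np.ndarray, n: int) -> Tree:
    nodes: dict[int, Tree] = {i: i for i in range(n)}
    for row, (a, b, h, _) in enumerate(Z):
        nodes[n + row] = (nodes[int(a)], nodes[int(b)], float(h))
    return nodes[n + len(Z) - 1]


def agglomerative_cluster(
    m: DistanceMatrix, method: str = "average", k_range: Iterable[int] = range(2, 11)
) -> ClusteringResult:
    """Agglomerative hierarchy with one of the standard joining functions."""
    if method not in AGGLOMERATIVE_LINKAGES:
        raise FvError(f"unknown linkage {method!r}; choose from {AGGLOMERATIVE_LINKAGES}")
    n = len(m)
    if n < 2:
        raise FvError("need at least 2 objects")
    Z = linkage(squareform(m.values, checks=False), method=method)
    tree = _linkage_to_tree(Z, n)
    labels_by_k: dict[int, np.ndarray] = {}
    sil_by_k: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= n:
            continue
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
        if len(np.unique(labels)) < 2:
            continue
        labels_by_k[k] = labels
        sil_by_k[k] = silhouette(m, labels)
    result = ClusteringResult(method, list(m.ids), tree, labels_by_k, sil_by_k)
    _choose_k(result)
    return result


def silhouette(m: DistanceMatrix, labels: np.ndarray) -> float:
    """Mean silhouette width of a flat partition (singletons contribute 0)."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise FvError("silhouette requires at least 2 clusters")
    if len(uniq) == len(labels):
        return 0.0  # every cluster a singleton; each contributes s = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s = silhouette_samples(m.values, labels, metric="precomputed")
    return float(np.mean(s))


def _choose_k(result: ClusteringResult) -> None:
    if not result.silhouette_by_k:
        result.degenerate = True
        result.chosen_k = None
        return
    best = max(result.silhouette_by_k.items(), key=lambda kv: (kv[1], -kv[0]))
    result.chosen_k = best[0]


def select_clustering(
    m: DistanceMatrix,
    methods: Sequence[str] = ("diana",) + AGGLOMERATIVE_LINKAGES,
    k_range: Iterable[int] = range(2, 11),
) -> ClusteringResult:
    """Evaluate every method x k and return the silhouette argmax.

    Ties are broken toward fewer clusters, then by method order.
    """
    if np.all(m.values == 0):
        warnings.warn("all distances are zero; clustering is degenerate", stacklevel=2)
        res = ClusteringResult("degenerate", list(m.ids), 0, {}, {}, None, True)
        return res
    k_range = list(k_range)
    results = []
    for method in methods:
        if method == "diana":
            results.append(diana_cluster(m, k_range))
        else:
            results.append(agglomerative_cluster(m, method, k_range))
    best: Optional[tuple[float, int, int, ClusteringResult]] = None
    for mi, res in enumerate(results):
        for k, s in res.silhouette_by_k.items():
            cand = (-s, k, mi)
            if best is None or cand < best[:3]:
                best = (-s, k, mi, res)
    if best is None:
        warnings.warn("no valid partition with k >= 2", stacklevel=2)
        res = ClusteringResult("degenerate", list(m.ids), 0, {}, {}, None, True)
        return res
    chosen = best[3]
    chosen.chosen_k = best[1]
    if chosen.silhouette <= 0:
        warnings.warn(
            "degenerate clustering: best silhouette is non-positive", stacklevel=2
        )
    return chosen


# ---------------------------------------------------------------------------
# Redundancy clustering


@dataclass
class IdentityCluster:
    representative: str
    members: list[str]
    centroid: Optional[str] = None


def greedy_identity_cluster(
    selections: Sequence[InterfaceSelection],
    threshold: float = 0.80,
    min_size: int = 3,
    resolutions: Optional[dict[str, float]] = None,
    distance_fn: Callable[[InterfaceSelection, InterfaceSelection], float] = interface_distance,
) -> list[IdentityCluster]:
    """Greedy incremental clustering on interface sequence identity.

    Items are processed best resolution first (ties by id) and join the
    first existing cluster whose representative shares >= ``threshold``
    identity over the 20 interface positions; otherwise they found a new
    cluster.  Clusters smaller than ``min_size`` are dropped.  Each kept
    cluster's centroid is the member minimising the summed structural
    distance to its co-members.
    """
    from .model import interface_identity

    resolutions = resolutions or {}
    by_id = {sel.structure_id: sel for sel in selections}
    order = sorted(
        by_id, key=lambda i: (resolutions.get(i, float("inf")), i)
    )
    clusters: list[IdentityCluster] = []
    for sid in order:
        sel = by_id[sid]
        placed = False
        for cl in clusters:
            if interface_identity(by_id[cl.representative], sel) >= threshold:
                cl.members.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(IdentityCluster(sid, [sid]))
    kept = [cl for cl in clusters if len(cl.members) >= min_size]
    for cl in kept:
        if len(cl.members) == 1:
            cl.centroid = cl.members[0]
            continue
        sums = {}
        for a in cl.members:
            sums[a] = sum(distance_fn(by_id[a], by_id[b]) for b in cl.members if b != a)
        cl.centroid = min(cl.members, key=lambda a: (sums[a], a))
    return kept


# ---------------------------------------------------------------------------
# Position importance


@dataclass
class PositionImportance:
    importances: pd.Series  # index: rendered PositionId, mean Gini decrease
    ranking: list[str]  # positions, most important first
    frequencies: pd.DataFrame  # cluster-conditional residue frequencies
    oob_error: float


def _sequence_symbol(pair: tuple[NumberedSequence, NumberedSequence], pos: PositionId) -> str:
    seq = pair[0] if pos.chain == "L" else pair[1]
    return seq.get(pos, GAP) or GAP


def gini_importance(
    sequences: Sequence[tuple[NumberedSequence, NumberedSequence]],
    labels: Sequence,
    n_trees: int = 500,
    seed: int = 0,
) -> PositionImportance:
    """Rank positions by mean Gini impurity decrease in a random forest.

    Sequences are one-hot encoded per (position, residue) with the gap as
    a 21st symbol; a position's importance is the summed impurity decrease
    of its indicator features (sqrt(p) features per split, ``n_trees``
    trees).  Also reports the out-of-bag classification error.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise FvError("need at least 2 classes")
    positions = sorted(
        {p for pair in sequences for seq in pair for p in seq.positions}
    )
    cols = {}
    for pos in positions:
        symbols = [_sequence_symbol(pair, pos) for pair in sequences]
        for sym in sorted(set(symbols)):
            cols[(pos.render(), sym)] = np.array([s == sym for s in symbols], dtype=float)
    X = np.column_stack(list(cols.values()))
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rf.fit(X, labels)
    imp = pd.Series(0.0, index=[p.render() for p in positions])
    for (pname, _), w in zip(cols.keys(), rf.feature_importances_):
        imp[pname] += w
    ranking = list(imp.sort_values(ascending=False).index)
    freqs = residue_frequencies(sequences, labels, positions)
    return PositionImportance(imp, ranking, freqs, 1.0 - float(rf.oob_score_))


def residue_frequencies(
    sequences: Sequence[tuple[NumberedSequence, NumberedSequence]],
    labels: Sequence,
    positions: Sequence[PositionId],
) -> pd.DataFrame:
    """Per-(cluster, position) residue counts and normalised frequencies."""
    rows = []
    labels = np.asarray(labels)
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        for pos in positions:
            symbols = [_sequence_symbol(sequences[i], pos) for i in idx]
            total = len(symbols)
            for sym in sorted(set(symbols)):
                c = symbols.count(sym)
                rows.append(
                    {
                        "cluster": lab,
                        "position": pos.render(),
                        "residue": sym,
                        "count": c,
                        "frequency": c / total,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Interface-type classifiers


def classify_by_rule(light: NumberedSequence) -> str:
    """Single-residue packing-mode rule: proline at L44 -> type A.

    A non-proline residue at L44 calls type B; an absent or gapped L44
    returns ``"unknown"``.
    """
    res = light.get(L44)
    if res is None or res == GAP:
        return "unknown"
    return "A" if res == "P" else "B"


@dataclass
class CentroidCall:
    label: str
    d_A: float
    d_B: float
    outlier: bool


def nearest_centroid_classify(
    sel: InterfaceSelection,
    centroids: dict[str, InterfaceSelection],
    outlier_cutoff: float = 0.25,
) -> CentroidCall:
    """Assign the packing mode of the nearer cluster centroid.

    Distances are ``1 - GDT_HA`` to each centroid; when both exceed
    ``outlier_cutoff`` the structure is flagged as packing like neither
    mode (the singleton-cluster situation).
    """
    d = {lab: interface_distance(sel, c) for lab, c in sorted(centroids.items())}
    label = min(sorted(d), key=lambda lab: d[lab])
    return CentroidCall(label, d.get("A", float("nan")), d.get("B", float("nan")), all(v > outlier_cutoff for v in d.values()))
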