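"""Patient clustering, neighbor-joining lineage, and gene subset assignment.

Patients are clustered on their binary upregulation profiles (Euclidean
distance on 0/1 rows, agglomerative linkage cut at k clusters).  Each
cluster is summarized by its mean upregulation profile — the per-gene
fraction of member patients carrying the upregulation — and an all-zero
profile stands in for the normal (pre-tumor) state.  Neighbor-joining
(Saitou-Nei) over the Euclidean distances among {cluster means, zero root}
yields the lineage tree; the cluster leaf closest to the normal leaf along
tree paths is the earliest subpopulation.

Every gene is then assigned to one of the 2^k − 1 nonzero binary subset
vectors by maximal cosine similarity between the vector and the gene's
per-cluster mean profile::

    similarity(p, v) = (p · v) / (||p||_2 ||v||_2)

Genes whose assigned subset includes the earliest cluster constitute the
early-burst set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from sklearn.metrics import silhouette_score

from .recurrence import UpregulationProfile

logger = logging.getLogger(__name__)

DEFAULT_K = 4
DEFAULT_LINKAGE = "ward"
ROOT_NAME = "normal"


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def pairwise_distance(profile: UpregulationProfile) -> pd.DataFrame:
    """Patient x patient Euclidean distance on binary profile columns.

    On 0/1 vectors this equals sqrt(Hamming count).
    """
    mat = profile.matrix.to_numpy().T.astype(float)  # patients x genes
    if mat.shape[0] < 2:
        raise ValueError("pairwise_distance requires at least 2 patients")
    d = squareform(pdist(mat, metric="euclidean"))
    pats = profile.patients
    return pd.DataFrame(d, index=pats, columns=pats)


@dataclass
class ClusterSet:
    """Patient partition plus per-cluster mean upregulation profiles."""

    labels: pd.Series                 # patient -> cluster label "C1".."Ck"
    mean_profiles: pd.DataFrame       # genes x clusters, fractions in [0,1]
    k: int
    linkage_method: str
    heights: np.ndarray = field(default_factory=lambda: np.array([]))
    silhouette: float = float("nan")

    def members(self, label: str) -> list[str]:
        return self.labels.index[self.labels == label].tolist()


def hierarchical_clusters(
    profile: UpregulationProfile,
    k: int = DEFAULT_K,
    linkage_method: str = DEFAULT_LINKAGE,
) -> ClusterSet:
    """Agglomerative clustering of patients cut into k groups.

    Labels are assigned C1..Ck in order of first patient appearance.  Mean
    profiles are column-wise means of member binary rows.  A silhouette
    score (on the Euclidean distances) is recorded to help justify k.
    """
    pats = profile.patients
    n = len(pats)
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n} patients")
    mat = profile.matrix.to_numpy().T.astype(float)
    cond = pdist(mat, metric="euclidean")
    Z = linkage(cond, method=linkage_method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    # stable relabeling by first appearance
    order: dict[int, str] = {}
    for lab in raw:
        if lab not in order:
            order[lab] = f"C{len(order) + 1}"
    labels = pd.Series([order[lab] for lab in raw], index=pats, name="cluster")

    means = {}
    for c in sorted(labels.unique(), key=lambda s: int(s[1:])):
        cols = labels.index[labels == c]
        means[c] = profile.matrix[cols].mean(axis=1)
    mean_profiles = pd.DataFrame(means)

    sil = float("nan")
    if 2 <= k < n:
        try:
            sil = float(silhouette_score(squareform(cond), raw, metric="precomputed"))
        except ValueError:
            pass
    return ClusterSet(
        labels=labels,
        mean_profiles=mean_profiles,
        k=k,
        linkage_method=linkage_method,
        heights=Z[:, 2].copy(),
        silhouette=sil,
    )


# ---------------------------------------------------------------------------
# neighbor-joining lineage
# ---------------------------------------------------------------------------

@dataclass
class LineageTree:
    """Weighted lineage tree over cluster taxa plus the normal root taxon."""

    tree: TreeNode
    taxa: list[str]
    negative_branches: list[tuple[str, float]] = field(default_factory=list)

    def newick(self) -> str:
        return str(self.tree).strip()

    def path_length(self, a: str, b: str) -> float:
        return float(self.tree.find(a).distance(self.tree.find(b)))


def neighbor_joining(dist: pd.DataFrame) -> tuple[TreeNode, list[tuple[str, float]]]:
    """Saitou-Nei neighbor-joining on a symmetric distance matrix.

    Returns the unrooted tree (as a TreeNode with a trifurcating root for
    n ≥ 3) and a list of (node, raw_length) for branches clamped from
    negative to zero.
    """
    names = list(dist.index)
    n = len(names)
    if n < 2:
        raise ValueError("neighbor_joining requires at least 2 taxa")
    D = dist.to_numpy(dtype=float).copy()
    nodes: dict[str, TreeNode] = {nm: TreeNode(name=nm) for nm in names}
    active = list(names)
    clamped: list[tuple[str, float]] = []
    counter = 0

    def clamp(node: TreeNode, length: float) -> None:
        if length < 0:
            clamped.append((node.name or "internal", float(length)))
            length = 0.0
        node.length = float(length)

    while len(active) > 2:
        m = len(active)
        sub = D
        total = sub.sum(axis=1)
        # Q-matrix; diagonal masked
        Q = (m - 2) * sub - total[:, None] - total[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        d_ij = sub[i, j]
        li = 0.5 * d_ij + (total[i] - total[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        counter += 1
        parent = TreeNode(name=f"n{counter}")
        ni, nj = nodes[active[i]], nodes[active[j]]
        clamp(ni, li)
        clamp(nj, lj)
        parent.extend([ni, nj])
        if d_ij == 0:
            logger.warning("identical taxa %s and %s joined at zero branch length",
                           active[i], active[j])
        # distances from the new node to the remaining taxa
        d_new = 0.5 * (sub[i, :] + sub[j, :] - d_ij)
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.empty((m - 1, m - 1))
        D[:-1, :-1] = sub[np.ix_(keep, keep)]
        D[-1, :-1] = d_new[keep]
        D[:-1, -1] = d_new[keep]
        D[-1, -1] = 0.0
        new_name = parent.name
        nodes[new_name] = parent
        active = [active[x] for x in keep] + [new_name]

    # final join of the last two nodes
    a, b = nodes[active[0]], nodes[active[1]]
    d_ab = float(D[0, 1])
    root = TreeNode(name="root")
    clamp(a, d_ab)
    b.length = 0.0
    root.extend([a, b])
    return root, clamped


def build_lineage(
    cluster_means: pd.DataFrame,
    include_root: bool = True,
) -> LineageTree:
    """Neighbor-joining lineage over cluster mean profiles (+ zero root).

    ``cluster_means`` is genes x clusters.  When ``include_root`` is set, an
    all-zero profile named ``normal`` is appended as the ancestral taxon.
    Distances are Euclidean between profile vectors.
    """
    profiles = cluster_means.copy()
    if include_root:
        profiles[ROOT_NAME] = 0.0
    taxa = list(profiles.columns)
    if len(taxa) < 2:
        raise ValueError("build_lineage requires at least 2 taxa")
    vecs = profiles.to_numpy().T
    D = squareform(pdist(vecs, metric="euclidean"))
    dist = pd.DataFrame(D, index=taxa, columns=taxa)
    tree, clamped = neighbor_joining(dist)
    for node, raw in clamped:
        logger.warning("negative NJ branch at %s (%.3g) clamped to 0", node, raw)
    return LineageTree(tree=tree, taxa=taxa, negative_branches=clamped)


def earliest_cluster(lineage: LineageTree) -> str:
    """Cluster leaf with the shortest tree-path distance to the normal leaf.

    Ties break toward the smallest cluster label, with a warning.
    """
    if ROOT_NAME not in lineage.taxa:
        raise ValueError("lineage tree has no normal root taxon")
    clusters = [t for t in lineage.taxa if t != ROOT_NAME]
    dists = {c: lineage.path_length(ROOT_NAME, c) for c in clusters}
    best = min(dists.values())
    winners = sorted([c for c, d in dists.items() if d == best])
    if len(winners) > 1:
        logger.warning("earliest-cluster tie among %s; choosing %s", winners, winners[0])
    return winners[0]


# ---------------------------------------------------------------------------
# subset assignment (cosine similarity)
# ---------------------------------------------------------------------------

def enumerate_subsets(k: int) -> list[tuple[int, ...]]:
    """All 2^k − 1 nonzero binary vectors of length k in ascending binary order.

    For k = 4 this runs (0,0,0,1), (0,0,1,0), ..., (1,1,1,1).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = []
    for i in range(1, 2**k):
        bits = tuple((i >> (k - 1 - j)) & 1 for j in range(k))
        out.append(bits)
    return out


@dataclass
class SubsetAssignment:
    """Per-gene best-matching cluster subset with its cosine similarity."""

    table: pd.DataFrame  # gene, subset (string of bits), similarity, unassigned
    subsets: list[tuple[int, ...]]
    cluster_order: list[str]

    def genes_in_subset_position(self, position: int) -> set[str]:
        """Genes whose assigned subset has a 1 at ``position`` (0-based)."""
        ok = self.table.loc[~self.table["unassigned"], "subset"]
        return set(ok.index[ok.str[position] == "1"])


def subset_assignment(
    gene_profiles: pd.DataFrame,
    cluster_order: list[str] | None = None,
) -> SubsetAssignment:
    """Assign each gene to the nonzero subset vector most parallel to it.

    ``gene_profiles`` is genes x clusters with per-cluster upregulation
    fractions.  Cosine similarity is computed against every candidate
    subset; ties prefer the subset with fewest ones, then ascending binary
    order.  All-zero profiles are unassigned.
    """
    if cluster_order is None:
        cluster_order = list(gene_profiles.columns)
    k = len(cluster_order)
    subsets = enumerate_subsets(k)
    V = np.array(subsets, dtype=float)               # (2^k-1) x k
    V_norm = V / np.linalg.norm(V, axis=1, keepdims=True)
    P = gene_profiles[cluster_order].to_numpy(dtype=float)
    p_norm = np.linalg.norm(P, axis=1)
    zero = p_norm == 0
    safe = np.where(zero, 1.0, p_norm)
    sims = (P / safe[:, None]) @ V_norm.T             # genes x subsets

    # argmax with tie-break: fewest ones, then ascending binary order.
    ones = V.sum(axis=1)
    order = np.lexsort((np.arange(len(subsets)), ones))  # stable: ones asc, index asc
    sims_ord = sims[:, order]
    best_ord = np.argmax(sims_ord == sims_ord.max(axis=1, keepdims=True), axis=1)
    best = order[best_ord]

    rows = []
    for gi, g in enumerate(gene_profiles.index):
        if zero[gi]:
            rows.append((g, "", np.nan, True))
        else:
            bits = "".join(str(b) for b in subsets[best[gi]])
            rows.append((g, bits, float(sims[gi, best[gi]]), False))
    table = pd.DataFrame(
        rows, columns=["gene", "subset", "similarity", "unassigned"]
    ).set_index("gene", drop=False)
    return SubsetAssignment(table=table, subsets=subsets, cluster_order=cluster_order)


def gene_cluster_profiles(
    profile: UpregulationProfile, clusters: ClusterSet, genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene, per-cluster upregulation fractions (Eq.-3 input vectors)."""
    mat = profile.matrix if genes is None else profile.matrix.loc[genes]
    cols = {}
    for c in clusters.mean_profiles.columns:
        members = clusters.members(c)
        cols[c] = mat[members].mean(axis=1)
    return pd.DataFrame(cols)


def early_burst_genes(
    assignments: SubsetAssignment,
    earliest: str,
    eea_set: set[str] | None = None,
) -> dict[str, set[str]]:
    """Two-tier early-burst call from subset assignments.

    ``inclusive``: genes whose assigned subset has a 1 at the earliest
    cluster's position (this includes the all-ones subset).  ``strict``:
    genes assigned exactly the singleton subset of the earliest cluster.
    When ``eea_set`` is given, both tiers are intersected with it.
    """
    pos = assignments.cluster_order.index(earliest)
    inclusive = assignments.genes_in_subset_position(pos)
    singleton = "".join("1" if i == pos else "0" for i in range(len(assignments.cluster_order)))
    tab = assignments.table
    strict = set(tab.index[(~tab["unassigned"]) & (tab["subset"] == singleton)])
    if eea_set is not None:
        inclusive &= set(eea_set)
        strict &= set(eea_set)
    return {"inclusive": inclusive, "strict": strict}
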