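"""Chemotaxonomic multivariate analysis and 16S phylogeny comparison.

The lipidome side: abundance matrices are log-transformed and scaled
(z-score within sample for clustering; sum-normalization + log for
ordination), hierarchically clustered under four linkage criteria,
ordinated by PCA, and screened for discriminant features with PLS-DA VIP
scores (NIPALS). The phylogeny side: p-distances with pairwise deletion
from a pre-aligned 16S FASTA, neighbor joining (Saitou-Nei) with
non-parametric bootstrap, and dendrogram-vs-tree concordance via the
adjusted Rand index at a k-cluster cut and the Robinson-Foulds distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

LINKAGES = ("complete", "single", "ward", "average")


# ---------------------------------------------------------------------------
# Matrix preparation
# ---------------------------------------------------------------------------

def prepare_matrix(abundances: pd.DataFrame, mode: str = "cluster") -> pd.DataFrame:
    """Transform a lipids x samples abundance matrix for analysis.

    ``cluster`` mode: log10 then z-score within each sample column (the
    scaling used upstream of hierarchical clustering). ``ordination``
    mode: divide each column by its sum, then log10 (the normalization
    used for PCA/PLS-DA). Zeros are replaced by half the smallest
    positive value in the matrix before the log; an all-zero column is an
    error, and a constant column in cluster mode falls back to sd = 1
    with a warning.
    """
    if mode not in ("cluster", "ordination"):
        raise ValueError(f"unknown mode {mode!r}")
    x = abundances.astype(float).copy()
    if (x.values < 0).any():
        raise ValueError("abundances must be non-negative before log transform")
    if (x.sum(axis=0) == 0).any():
        bad = list(x.columns[x.sum(axis=0) == 0])
        raise ValueError(f"all-zero sample column(s): {bad}")
    positive = x.values[x.values > 0]
    half_min = positive.min() / 2.0
    x = x.mask(x == 0, half_min)
    if mode == "ordination":
        x = x / x.sum(axis=0)
        return np.log10(x)
    x = np.log10(x)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    if (sd == 0).any():
        warnings.warn(
            f"constant sample column(s) {list(x.columns[sd == 0])}; "
            "sd fallback to 1"
        )
        sd = sd.mask(sd == 0, 1.0)
    return (x - mean) / sd


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative merge tree over sample columns."""

    linkage_matrix: np.ndarray
    labels: list[str]
    method: str

    def cut(self, k: int) -> dict[str, int]:
        """Cluster assignment (label -> cluster id) at k clusters."""
        assign = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def to_newick(self) -> str:
        """Newick string with cophenetic merge heights as node depths."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def hcluster(
    matrix: pd.DataFrame, linkage: str = "complete", metric: str = "euclidean"
) -> Dendrogram:
    """Cluster the sample columns of a prepared matrix.

    ``ward`` follows the classical Ward criterion on Euclidean distances.
    Ties are broken deterministically (lower column index merges first,
    scipy convention).
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if matrix.shape[1] < 2:
        raise ValueError("need at least two columns to cluster")
    x = matrix.T.values  # observations = samples
    if np.isnan(x).any():
        raise ValueError("matrix contains NaN")
    if linkage == "ward":
        z = hierarchy.linkage(x, method="ward", metric="euclidean")
    else:
        z = hierarchy.linkage(pdist(x, metric=metric), method=linkage)
    return Dendrogram(z, list(matrix.columns), linkage)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

def pca(matrix: pd.DataFrame, n_components: int = 2):
    """PCA over sample columns (features are variables).

    Returns (scores: samples x k, loadings: features x k, explained
    variance fractions). Implemented by SVD of the column-centered data;
    fractions are non-increasing and sum to <= 1.
    """
    x = matrix.T.values.astype(float)          # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    rank = np.linalg.matrix_rank(x)
    if n_components > rank:
        raise ValueError(f"n_components {n_components} exceeds rank {rank}")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    var = s**2 / (x.shape[0] - 1 if x.shape[0] > 1 else 1)
    explained = var[:n_components] / var.sum()
    scores = pd.DataFrame(
        scores, index=matrix.columns,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    loadings = pd.DataFrame(
        loadings, index=matrix.index,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    return scores, loadings, explained


def plsda_vip(
    matrix: pd.DataFrame,
    class_labels: dict[str, str],
    n_components: int = 2,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> pd.Series:
    """Variable-importance-in-projection scores from PLS-DA (NIPALS).

    Samples (columns of ``matrix``) are autoscaled per feature; the class
    membership is one-hot encoded. VIP_j = sqrt(p * sum_a w_ja^2 SSY_a /
    sum_a SSY_a) with normalized weight vectors w_a and per-component
    explained Y-variance SSY_a; mean(VIP^2) = 1 by construction.
    """
    samples = list(matrix.columns)
    classes = sorted(set(class_labels[s] for s in samples))
    if len(classes) < 2:
        raise ValueError("PLS-DA requires at least two classes")
    for c in classes:
        if sum(class_labels[s] == c for s in samples) < 2:
            raise ValueError(f"class {c!r} has fewer than two samples")
    x = matrix.T.values.astype(float)          # samples x features
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    x = x / sd
    y = np.array([[1.0 if class_labels[s] == c else 0.0 for c in classes]
                  for s in samples])
    y = y - y.mean(axis=0)

    n, p = x.shape
    n_components = min(n_components, n - 1, p)
    weights, t_scores, ssy = [], [], []
    xa, ya = x.copy(), y.copy()
    for _ in range(n_components):
        u = ya[:, np.argmax(np.var(ya, axis=0))]
        t_old = None
        for _ in range(max_iter):
            w = xa.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w = w / nw
            t = xa @ w
            q = ya.T @ t / (t @ t)
            u = ya @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                break
            t_old = t
        if np.linalg.norm(w) == 0:
            break
        pl = xa.T @ t / (t @ t)
        xa = xa - np.outer(t, pl)
        ya = ya - np.outer(t, q)
        weights.append(w)
        t_scores.append(t)
        ssy.append(float((t @ t) * (q @ q)))
    w = np.array(weights)                       # a x p
    ssy_arr = np.array(ssy)
    if ssy_arr.sum() == 0:
        raise ValueError("PLS-DA extracted no explanatory components")
    vip = np.sqrt(p * (w**2 * ssy_arr[:, None]).sum(axis=0) / ssy_arr.sum())
    return pd.Series(vip, index=matrix.index, name="VIP").sort_values(
        ascending=False
    )


# ---------------------------------------------------------------------------
# Phylogeny: p-distance, neighbor joining, bootstrap
# ---------------------------------------------------------------------------

def read_alignment(path_or_handle) -> dict[str, str]:
    """Read a pre-aligned FASTA; all sequences must share one length."""
    records = list(SeqIO.parse(path_or_handle, "fasta"))
    if not records:
        raise ValueError("empty alignment")
    seqs = {r.id: str(r.seq).upper() for r in records}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    return seqs


_GAPS = set("-.?NX")


def p_distance(seqs: dict[str, str]) -> pd.DataFrame:
    """Pairwise p-distance with pairwise deletion of gap/ambiguous sites."""
    taxa = list(seqs)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[taxa[i]], seqs[taxa[j]]
            diffs = valid = 0
            for ca, cb in zip(a, b):
                if ca in _GAPS or cb in _GAPS:
                    continue
                valid += 1
                diffs += ca != cb
            if valid == 0:
                raise ValueError(
                    f"no comparable sites between {taxa[i]} and {taxa[j]}"
                )
            d[i, j] = d[j, i] = diffs / valid
    return pd.DataFrame(d, index=taxa, columns=taxa)


def nj_tree(dist: pd.DataFrame) -> str:
    """Neighbor joining (Saitou-Nei), returned as an unrooted Newick string.

    Standard Q-matrix agglomeration with the usual branch-length formulas;
    negative branch lengths are clamped to zero. Requires >= 3 taxa and a
    symmetric zero-diagonal matrix.
    """
    taxa = list(dist.index)
    if len(taxa) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if not np.allclose(dist.values, dist.values.T) or np.any(np.diag(dist.values)):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    d = {(a, b): float(dist.loc[a, b]) for a in taxa for b in taxa}
    nodes = {t: t for t in taxa}  # node -> newick fragment
    active = list(taxa)
    counter = 0
    while len(active) > 2:
        n = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best, best_q = None, np.inf
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * d[(a, b)] - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        a, b = best
        la = 0.5 * d[(a, b)] + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = d[(a, b)] - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = f"__node{counter}"
        counter += 1
        nodes[new] = f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g})"
        for c in active:
            if c in (a, b):
                continue
            d[(new, c)] = d[(c, new)] = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
        d[(new, new)] = 0.0
        active = [c for c in active if c not in (a, b)] + [new]
    a, b = active
    lab = max(d[(a, b)], 0.0)
    return f"({nodes[a]}:{lab / 2.0:.10g},{nodes[b]}:{lab / 2.0:.10g});"


def tree_bipartitions(newick: str) -> set[frozenset]:
    """Non-trivial bipartitions (as smaller-leafset frozensets) of a tree."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(side) < len(taxa) - 1:
            other = taxa - side
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def bootstrap_support(
    seqs: dict[str, str],
    n_replicates: int = 1000,
    seed: int | None = None,
) -> dict[frozenset, float]:
    """Bootstrap support for each bipartition of the full-alignment NJ tree.

    Alignment columns are resampled with replacement; support is the
    fraction of replicate NJ trees containing each bipartition. Taxon
    input order does not affect the result for a given seed: the column
    resampling is the only stochastic element.
    """
    seqs = {t: seqs[t] for t in sorted(seqs)}
    ref = tree_bipartitions(nj_tree(p_distance(seqs)))
    length = len(next(iter(seqs.values())))
    rng = np.random.default_rng(seed)
    counts = {bp: 0 for bp in ref}
    taxa = list(seqs)
    arr = np.array([list(seqs[t]) for t in taxa])
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = {
            t: "".join(arr[i, cols]) for i, t in enumerate(taxa)
        }
        bps = tree_bipartitions(nj_tree(p_distance(resampled)))
        for bp in counts:
            if bp in bps:
                counts[bp] += 1
    return {bp: c / n_replicates for bp, c in counts.items()}


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def robinson_foulds(newick_a: str, newick_b: str) -> int:
    """Unrooted symmetric-difference (RF) distance between two trees."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(ta, tb))


def concordance(
    dendrogram: Dendrogram,
    reference_labels: dict[str, str],
    k: int,
    reference_newick: str | None = None,
) -> dict[str, float]:
    """Agreement between a lipidome dendrogram and a reference phylogeny.

    ARI compares the k-cut cluster assignment with the reference taxon
    labels (k = 1 gives ARI 0 by convention); if a reference tree is
    supplied, the unrooted RF distance between it and the dendrogram
    topology is reported as well.
    """
    leaves = set(dendrogram.labels)
    if leaves != set(reference_labels):
        raise ValueError("dendrogram and reference must share the leaf set")
    assign = dendrogram.cut(k)
    order = dendrogram.labels
    if k <= 1:
        ari = 0.0
    else:
        ari = float(adjusted_rand_score(
            [reference_labels[t] for t in order],
            [assign[t] for t in order],
        ))
    out = {"ari": ari, "k": k}
    if reference_newick is not None:
        out["rf"] = robinson_foulds(dendrogram.to_newick(), reference_newick)
    return out
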