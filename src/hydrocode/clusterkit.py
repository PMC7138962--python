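"""Hierarchical and fuzzy clustering of amino acids by hydrophobicity and polarity.

The amino-acid pipeline clusters the 20 residues on two standardized
variables — the hydrophobicity log10 Kw>c at one temperature and the Davis
2nd-codon-base polarity score — with Manhattan dissimilarities.  Ward and
UPGMA trees are built by Lance-Williams updates on the supplied
dissimilarities (Ward applied to non-Euclidean distances is deliberate and
documented).  The Kaufman-Rousseeuw agglomerative coefficient, FANNY fuzzy
partitioning and average silhouette widths quantify how cleanly the residues
fall into the three 2nd-base groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .codebook import AMINO_ACIDS, DAVIS_SCORES
from .scales import get_scale, logkwc_scale, standardize

__all__ = [
    "Dissimilarity",
    "Dendrogram",
    "FuzzyPartition",
    "AminoAcidClustering",
    "dissimilarity",
    "agnes",
    "agglomerative_coefficient",
    "fanny",
    "avg_silhouette",
    "cophenetic_correlation",
    "cut_tree",
    "amino_acid_clustering",
]

_METRICS = {"manhattan": "cityblock", "euclidean": "euclidean"}


@dataclass(frozen=True)
class Dissimilarity:
    """Symmetric pairwise-dissimilarity matrix with zero diagonal."""

    matrix: np.ndarray
    metric: str
    labels: tuple[str, ...] | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


def dissimilarity(data: np.ndarray, metric: str = "manhattan", labels=None) -> Dissimilarity:
    """Pairwise distances between the rows of ``data`` under the named metric."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite entries in data")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    mat = squareform(pdist(data, _METRICS[metric]))
    return Dissimilarity(matrix=mat, metric=metric, labels=tuple(labels) if labels is not None else None)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree in scipy linkage form plus leaf labels."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaf_labels: tuple[str, ...]
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        n = self.n_leaves
        Z = self.linkage
        height = {i: 0.0 for i in range(n)}
        node = {i: self.leaf_labels[i] for i in range(n)}
        for k, (i, j, h, _) in enumerate(Z):
            i, j = int(i), int(j)
            bi = max(h - height[i], 0.0)
            bj = max(h - height[j], 0.0)
            node[n + k] = f"({node[i]}:{bi:.6g},{node[j]}:{bj:.6g})"
            height[n + k] = h
        return node[n + len(Z) - 1] + ";"


def agnes(diss: Dissimilarity, method: str = "ward") -> Dendrogram:
    """Agglomerative clustering on a dissimilarity matrix.

    ``ward`` applies the Lance-Williams Ward update to the given
    dissimilarities (whatever their metric); ``upgma`` is average linkage.
    """
    if diss.n < 2:
        raise ValueError("need at least 2 items")
    scipy_method = {"ward": "ward", "upgma": "average"}.get(method)
    if scipy_method is None:
        raise ValueError(f"unknown linkage method {method!r}")
    Z = hierarchy.linkage(diss.condensed(), method=scipy_method)
    labels = diss.labels or tuple(str(i) for i in range(diss.n))
    return Dendrogram(linkage=Z, leaf_labels=labels, method=method)


def agglomerative_coefficient(dend: Dendrogram) -> float:
    """Kaufman-Rousseeuw AC: mean over leaves of 1 - first-merge height / final height."""
    Z = dend.linkage
    n = dend.n_leaves
    final = Z[-1, 2]
    if final <= 0:
        raise ValueError("degenerate tree: final merge height is zero")
    first = np.zeros(n)
    seen = np.zeros(n, dtype=bool)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k, (i, j, h, _) in enumerate(Z):
        merged = members[int(i)] + members[int(j)]
        for leaf in merged:
            if not seen[leaf]:
                first[leaf] = h
                seen[leaf] = True
        members[n + k] = merged
    return float(np.mean(1.0 - first / final))


def cut_tree(dend: Dendrogram, k: int) -> np.ndarray:
    """Labels 0..k-1 from cutting the tree into k clusters (by merge height/order)."""
    flat = hierarchy.fcluster(dend.linkage, t=k, criterion="maxclust")
    return np.asarray(flat) - 1


def cophenetic_correlation(dend: Dendrogram, diss: Dissimilarity) -> float:
    """Pearson r between the original and cophenetic distances."""
    coph = hierarchy.cophenet(dend.linkage)
    orig = diss.condensed()
    return float(np.corrcoef(orig, coph)[0, 1])


def avg_silhouette(labels: np.ndarray, diss: Dissimilarity) -> float:
    """Average silhouette width of a crisp partition on a dissimilarity matrix.

    Per point: (b - a)/max(a, b) with a the mean within-cluster dissimilarity
    and b the smallest mean dissimilarity to another cluster; points in
    singleton clusters contribute 0.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    return float(silhouette_score(diss.matrix, labels, metric="precomputed"))


@dataclass
class FuzzyPartition:
    """FANNY result: membership matrix, crisp labels and their silhouette."""

    membership: np.ndarray  # (n, k), rows sum to 1
    k: int
    objective: float
    n_iter: int
    converged: bool
    crisp_labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.crisp_labels = np.argmax(self.membership, axis=1)


def _fanny_objective(t: np.ndarray, D: np.ndarray) -> float:
    # t = squared memberships, shape (n, k)
    num = np.einsum("iv,jv,ij->v", t, t, D)
    den = 2.0 * t.sum(axis=0)
    return float(np.sum(num / den))


def fanny(
    diss: Dissimilarity,
    k: int,
    exponent: float = 2.0,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> FuzzyPartition:
    """Kaufman-Rousseeuw fuzzy clustering on a dissimilarity matrix.

    Minimizes sum_v [sum_ij u_iv^2 u_jv^2 d_ij] / [2 sum_j u_jv^2] by cyclic
    membership updates (memberships proportional to inverse gradient, clamped
    to the simplex).  Initialization is deterministic: crisp UPGMA k-cut
    labels softened to 0.7/uniform, so repeated runs are identical.
    """
    if exponent != 2.0:
        raise NotImplementedError("only the classical exponent 2 is implemented")
    n = diss.n
    if not 2 <= k < n:
        raise ValueError("need 2 <= k < n")
    D = diss.matrix
    if np.allclose(D, 0):
        u = np.full((n, k), 1.0 / k)
        return FuzzyPartition(membership=u, k=k, objective=0.0, n_iter=0, converged=True)

    init_labels = cut_tree(agnes(diss, "upgma"), k)
    u = np.full((n, k), 0.3 / (k - 1))
    u[np.arange(n), init_labels] = 0.7

    eps = 1e-12
    prev_obj = np.inf
    converged = False
    for it in range(1, max_iter + 1):
        t = u**2
        for i in range(n):
            sums = t.sum(axis=0)  # includes i
            # gradient of the objective wrt t_iv
            num_v = np.einsum("jv,j->v", t, D[i])  # sum_j t_jv d_ij
            cluster_cost = np.einsum("jv,lv,jl->v", t, t, D)  # sum_jl t_jv t_lv d_jl
            e = num_v / np.maximum(sums, eps) - cluster_cost / np.maximum(2.0 * sums**2, eps)
            if np.any(e <= eps):
                # point sits on (or past) a cluster centre: assign crisp
                row = np.zeros(k)
                row[int(np.argmin(e))] = 1.0
            else:
                inv = 1.0 / e
                row = inv / inv.sum()
            u[i] = row
            t[i] = row**2
        obj = _fanny_objective(u**2, D)
        if np.isfinite(prev_obj) and abs(prev_obj - obj) <= tol * max(1.0, abs(prev_obj)):
            converged = True
            break
        prev_obj = obj
    if not converged:
        warnings.warn(f"fanny did not converge in {max_iter} iterations; returning best-so-far")
    return FuzzyPartition(membership=u, k=k, objective=obj, n_iter=it, converged=converged)


@dataclass(frozen=True)
class AminoAcidClustering:
    """Result of the two-variable amino-acid clustering at one temperature."""

    temperature_C: int
    groups: tuple[frozenset[str], ...]
    agglomerative_coefficient: float
    avg_silhouette_width: float
    dendrogram: Dendrogram
    fuzzy: FuzzyPartition

    def group_of(self, aa: str) -> int:
        for g, members in enumerate(self.groups):
            if aa in members:
                return g
        raise KeyError(aa)


def amino_acid_clustering(
    temperature: int = 25,
    standardization: str = "kr_mad",
    metric: str = "manhattan",
) -> AminoAcidClustering:
    """Cluster the 20 amino acids into 3 groups on (log10 Kw>c, Davis score).

    Both variables are standardized, Manhattan dissimilarities are clustered
    by Ward (tree, AC, k=3 cut) and by FANNY (k=3, silhouette of the crisp
    labels).  With either temperature the cut recovers the three 2nd-codon-
    base groups: nonpolar {F,L,I,M,V}, neutral {S,P,T,A,C,W,R,G}, polar
    {Y,H,Q,N,K,D,E}.
    """
    hydro = logkwc_scale(temperature)
    davis = get_scale("davis")
    order = AMINO_ACIDS
    X = np.column_stack(
        [standardize(hydro.vector(order), standardization), standardize(davis.vector(order), standardization)]
    )
    diss = dissimilarity(X, metric=metric, labels=order)
    dend = agnes(diss, method="ward")
    ac = agglomerative_coefficient(dend)
    labels = cut_tree(dend, 3)
    fz = fanny(diss, k=3)
    sil = avg_silhouette(fz.crisp_labels, diss)
    groups = tuple(
        frozenset(aa for aa, lab in zip(order, labels) if lab == g) for g in sorted(set(labels))
    )
    return AminoAcidClustering(
        temperature_C=int(temperature),
        groups=groups,
        agglomerative_coefficient=ac,
        avg_silhouette_width=sil,
        dendrogram=dend,
        fuzzy=fz,
    )


#: The three 2nd-codon-base groups the pipeline is expected to recover.
SECOND_BASE_GROUPS = (
    frozenset("FLIMV"),  # nonpolar, 2nd base U
    frozenset("SPTACWRG"),  # neutral, 2nd base C/G
    frozenset("YHQNKDE"),  # polar, 2nd base A
)

assert {aa for g in SECOND_BASE_GROUPS for aa in g} == set(AMINO_ACIDS)
assert all(
    {DAVIS_SCORES[aa] for aa in g} == {s} for g, s in zip(SECOND_BASE_GROUPS, (1, 0, -1))
)
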