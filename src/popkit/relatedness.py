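"""Kinship, population structure and family partitioning.

* VanRaden genomic relationship matrix G = ZZ' / 2 Σ p_i (1 - p_i), with Z the
  allele-dosage matrix centered at twice the sample allele frequency and
  missing calls imputed to the center (zero contribution).
* Identity-by-state genetic distance D = 1 - (0.5 IBS1 + IBS2) / N over the
  markers non-missing in both members of each pair.
* PCA of G (eigendecomposition, scores scaled by sqrt(eigenvalue)).
* Classical neighbor-joining on D, with a deterministic lowest-index
  tie-break, exported as Newick.
* Family partition: connected components of the graph with edges where
  G_ij >= threshold (default 0.1), numbered along the NJ leaf order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import GenotypeMatrix


def vanraden_g(gm: GenotypeMatrix,
               freqs: np.ndarray | None = None) -> np.ndarray:
    """VanRaden G matrix from 0/1/2 dosages.

    Allele frequencies default to the sample's own (missing calls excluded);
    pass ``freqs`` to center on reference/base-population frequencies instead,
    which avoids deflation when the sample is itself strongly family
    structured.  Monomorphic markers carry no information and are dropped
    with a warning.
    """
    p = gm.allele_frequencies() if freqs is None else np.asarray(freqs, float)
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(f"dropping {int((~poly).sum())} monomorphic/empty markers "
                      "from G")
    p = p[poly]
    calls = gm.calls[:, poly].astype(float)
    z = np.where(calls >= 0, calls, 2 * p) - 2 * p
    denom = 2.0 * np.sum(p * (1 - p))
    if denom == 0:
        raise ValueError("no polymorphic markers; G undefined")
    return z @ z.T / denom


@dataclass
class IBSResult:
    distance: np.ndarray       # D = 1 - D_ST, zero diagonal
    ibs0: np.ndarray
    ibs1: np.ndarray
    ibs2: np.ndarray
    n_compared: np.ndarray


def ibs_distance(gm: GenotypeMatrix) -> IBSResult:
    """Pairwise IBS sharing and genetic distance D.

    Per pair, only markers called in both individuals are compared;
    IBS = 2 - |g_i - g_j| classifies each locus as sharing 0, 1 or 2 alleles.
    """
    n = gm.n_samples
    calls = gm.calls
    obs = calls >= 0
    shape = (n, n)
    ibs = [np.zeros(shape, dtype=np.int64) for _ in range(3)]
    n_cmp = np.zeros(shape, dtype=np.int64)
    for i in range(n):
        both = obs[i] & obs[i + 1:]
        diff = np.abs(calls[i + 1:] - calls[i])
        for s in range(3):
            cnt = ((diff == 2 - s) & both).sum(axis=1)
            ibs[s][i, i + 1:] = cnt
            ibs[s][i + 1:, i] = cnt
        nc = both.sum(axis=1)
        n_cmp[i, i + 1:] = nc
        n_cmp[i + 1:, i] = nc
    if n > 1 and (n_cmp + np.eye(n, dtype=np.int64) == 0).any():
        raise ValueError("a sample pair shares no called markers; D undefined")
    own = obs.sum(axis=1)
    np.fill_diagonal(n_cmp, own)
    np.fill_diagonal(ibs[2], own)
    with np.errstate(invalid="ignore"):
        d_st = (0.5 * ibs[1] + ibs[2]) / n_cmp
    d = 1.0 - d_st
    np.fill_diagonal(d, 0.0)
    return IBSResult(d, ibs[0], ibs[1], ibs[2], n_cmp)


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    coordinates: np.ndarray           # n x k scores
    explained_fraction: np.ndarray


def grm_pca(g: np.ndarray, k: int = 2) -> PCAResult:
    """Eigendecomposition of the (symmetric) GRM.

    Scores are eigenvectors scaled by sqrt(max(eigenvalue, 0)); explained
    fractions are over the positive part of the spectrum.  For determinism
    across backends, each eigenvector's largest-magnitude entry is made
    positive.
    """
    g = np.asarray(g, dtype=float)
    n = g.shape[0]
    if g.shape != (n, n) or not np.allclose(g, g.T, atol=1e-8):
        raise ValueError("G must be square and symmetric")
    if k > n:
        raise ValueError(f"k={k} exceeds matrix size {n}")
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(n):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    pos_sum = np.clip(vals, 0, None).sum()
    explained = np.clip(vals, 0, None) / pos_sum if pos_sum > 0 else np.zeros(n)
    scores = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0, None))
    return PCAResult(vals, scores, explained)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(distance: np.ndarray, labels: list[str] | None = None) -> str:
    """Classical Saitou–Nei neighbor joining; returns a Newick string.

    Ties in the Q criterion join the lexicographically lowest index pair, so
    the topology is deterministic.  On additive distances the tree's path
    lengths reproduce the input exactly.
    """
    d = np.array(distance, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if labels is None:
        labels = [f"t{i}" for i in range(n)]
    if n == 1:
        return f"{labels[0]};"
    if n == 2:
        return f"({labels[0]}:{d[0, 1] / 2:.10g},{labels[1]}:{d[0, 1] / 2:.10g});"
    nodes = list(labels)
    active = list(range(n))
    dm = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    next_id = n
    subtree = {i: nodes[i] for i in range(n)}
    while len(active) > 3:
        m = len(active)
        r = {i: sum(dm[i, j] for j in active if j != i) for i in active}
        best, best_q = None, np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dm[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * dm[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = dm[i, j] - li
        u = next_id
        next_id += 1
        subtree[u] = f"({subtree[i]}:{li:.10g},{subtree[j]}:{lj:.10g})"
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dm[i, k] + dm[j, k] - dm[i, j])
            dm[u, k] = dm[k, u] = duk
        dm[u, u] = 0.0
        active = [k for k in active if k not in (i, j)] + [u]
    i, j, k = active
    # three-point formulas for the final star
    li = 0.5 * (dm[i, j] + dm[i, k] - dm[j, k])
    lj = 0.5 * (dm[i, j] + dm[j, k] - dm[i, k])
    lk = 0.5 * (dm[i, k] + dm[j, k] - dm[i, j])
    return (f"({subtree[i]}:{li:.10g},{subtree[j]}:{lj:.10g},"
            f"{subtree[k]}:{lk:.10g});")


def nj_leaf_order(newick: str) -> list[str]:
    """Leaf labels in the order they appear along the Newick string."""
    from skbio import TreeNode
    from io import StringIO

    tree = TreeNode.read(StringIO(newick))
    return [t.name for t in tree.tips()]


# ---------------------------------------------------------------------------
# Family partition
# ---------------------------------------------------------------------------

@dataclass
class FamilyPartition:
    family_id: list[int]              # per individual, 1-based
    nj_newick: str

    def as_frame(self, samples: list[str]) -> pd.DataFrame:
        return pd.DataFrame({"individual": samples, "family": self.family_id})


def partition_families(
    g: np.ndarray,
    samples: list[str],
    threshold: float = 0.1,
    distance: np.ndarray | None = None,
    method: str = "components",
) -> FamilyPartition:
    """Partition individuals into families by genomic relatedness.

    ``components`` (default): connected components of the graph with edges
    where G_ij >= threshold — every within-family pair is then linked by a
    chain of relationships at or above the criterion.  ``complete`` instead
    cuts a complete-linkage dendrogram so that all pairs within a family meet
    the criterion directly.  Families are numbered by their first member along
    the NJ leaf order of the distance matrix (or sample order if no distance
    is supplied).
    """
    n = len(samples)
    if method == "components":
        graph = nx.Graph()
        graph.add_nodes_from(range(n))
        ii, jj = np.nonzero(np.triu(g >= threshold, k=1))
        graph.add_edges_from(zip(ii.tolist(), jj.tolist()))
        comp_of = {}
        for comp in nx.connected_components(graph):
            for node in comp:
                comp_of[node] = min(comp)
    elif method == "complete":
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        sim_d = np.clip(np.max(g) - g, 0, None)
        np.fill_diagonal(sim_d, 0)
        link = linkage(squareform(sim_d, checks=False), method="complete")
        flat = fcluster(link, t=float(np.max(g) - threshold), criterion="distance")
        comp_of = {}
        for node, cl in enumerate(flat):
            comp_of[node] = min(i for i, c in enumerate(flat) if c == cl)
    else:
        raise ValueError("method must be 'components' or 'complete'")

    if distance is not None:
        newick = nj_tree(distance, samples)
        order = [samples.index(name) for name in nj_leaf_order(newick)]
    else:
        newick = ""
        order = list(range(n))
    fam_number: dict[int, int] = {}
    for node in order:
        root = comp_of[node]
        if root not in fam_number:
            fam_number[root] = len(fam_number) + 1
    family_id = [fam_number[comp_of[i]] for i in range(n)]
    return FamilyPartition(family_id, newick)
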