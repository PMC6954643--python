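"""SNV–SNV network construction and graph Laplacians.

Variants are first classified as *damaging* (high/moderate transcript
impact, predicted deleterious, or a known trait association) or
*candidate* (everything else).  Two SNVs are connected when they are
harboured by the same gene; damaging SNVs in different genes are
additionally connected when the two genes' proteins interact.  Within-gene
edges are down-weighted by 1/(N−1), N being the gene's variant count, so
that a candidate SNV's within-gene degree is 1 regardless of how many
variants the gene harbours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

IMPACT_CLASSES = ("high", "moderate", "low", "modifier")
DAMAGING_IMPACTS = ("high", "moderate")


def classify_variants(annotations: pd.DataFrame) -> np.ndarray:
    """Label each SNV "damaging" or "candidate" from its annotation row.

    A variant is damaging iff its impact class is high/moderate, OR it is
    predicted deleterious, OR it has a known trait association.
    """
    impact = annotations["impact_class"].astype(str).str.lower()
    bad = ~impact.isin(IMPACT_CLASSES)
    if bad.any():
        rows = annotations.index[bad].tolist()[:10]
        raise ValueError(f"unknown impact_class values at rows {rows}")
    damaging = (
        impact.isin(DAMAGING_IMPACTS)
        | annotations["predicted_deleterious"].astype(bool)
        | annotations["known_association"].astype(bool)
    )
    return np.where(damaging.to_numpy(), "damaging", "candidate")


@dataclass
class SnvNetwork:
    """Weighted undirected SNV–SNV graph aligned with the genotype matrix.

    snv_ids : node order, identical to the genotype matrix row order
    classes : "damaging"/"candidate" per node
    genes : harbouring gene per node
    W : symmetric non-negative adjacency with zero diagonal
    """

    snv_ids: list[str]
    classes: np.ndarray
    genes: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        W = self.W
        if W.shape[0] != W.shape[1] or W.shape[0] != len(self.snv_ids):
            raise ValueError("adjacency shape inconsistent with node list")
        if not np.allclose(W, W.T):
            raise ValueError("adjacency must be symmetric")
        if (W < 0).any():
            raise ValueError("negative edge weights")
        if np.abs(np.diag(W)).max(initial=0.0) > 0:
            raise ValueError("adjacency diagonal must be zero")

    @property
    def degree(self) -> np.ndarray:
        return self.W.sum(axis=1)

    def to_edge_frame(self) -> pd.DataFrame:
        i, j = np.nonzero(np.triu(self.W, k=1))
        return pd.DataFrame(
            {
                "snv_a": [self.snv_ids[a] for a in i],
                "snv_b": [self.snv_ids[b] for b in j],
                "weight": self.W[i, j],
            }
        )


def build_snv_network(
    classes: Sequence[str] | np.ndarray,
    snv_genes: Mapping[str, str] | Sequence[str],
    ppi_edges: Iterable[tuple[str, str]],
    snv_ids: Sequence[str],
    cross_gene_weight: str = "unit",
    cross_gene_mode: str = "ppi",
) -> SnvNetwork:
    """Assemble the weighted SNV–SNV adjacency.

    Parameters
    ----------
    classes : per-SNV "damaging"/"candidate" labels, in ``snv_ids`` order.
    snv_genes : mapping snv_id → gene (or a gene sequence in order).
    ppi_edges : undirected gene pairs whose proteins interact.
    cross_gene_weight : "unit" gives damaging–damaging cross-gene edges
        weight 1; "scaled" uses 1/sqrt((N_a−1)(N_b−1)) with per-gene
        variant counts (falling back to 1 for single-variant genes).
    cross_gene_mode : "ppi" restricts damaging–damaging edges to
        PPI-interacting gene pairs (default); "all" connects damaging
        variants across every pair of distinct genes.
    """
    snv_ids = list(snv_ids)
    n = len(snv_ids)
    classes = np.asarray(classes)
    if len(classes) != n:
        raise ValueError("classes and snv_ids length mismatch")
    if isinstance(snv_genes, Mapping):
        missing = [s for s in snv_ids if s not in snv_genes]
        if missing:
            raise ValueError(f"SNVs without gene mapping: {missing[:10]}")
        genes = np.asarray([snv_genes[s] for s in snv_ids])
    else:
        genes = np.asarray(list(snv_genes))
        if len(genes) != n:
            raise ValueError("gene list and snv_ids length mismatch")

    W = np.zeros((n, n))
    gene_index: dict[str, np.ndarray] = {}
    for g in np.unique(genes):
        gene_index[g] = np.flatnonzero(genes == g)

    # (a) within-gene edges at weight 1/(N-1); single-SNV genes stay isolated
    for g, idx in gene_index.items():
        N = len(idx)
        if N < 2:
            continue
        w = 1.0 / (N - 1)
        W[np.ix_(idx, idx)] = w
    np.fill_diagonal(W, 0.0)

    # (b) damaging-damaging edges across distinct genes
    ppi = {frozenset(e) for e in ppi_edges if e[0] != e[1]}
    dmg = np.flatnonzero(classes == "damaging")
    counts = {g: len(idx) for g, idx in gene_index.items()}
    for a_pos, i in enumerate(dmg):
        for j in dmg[a_pos + 1 :]:
            ga, gb = genes[i], genes[j]
            if ga == gb:
                continue
            if cross_gene_mode == "ppi" and frozenset((ga, gb)) not in ppi:
                continue
            if cross_gene_weight == "scaled":
                na, nb = max(counts[ga] - 1, 1), max(counts[gb] - 1, 1)
                w = 1.0 / np.sqrt(na * nb)
            else:
                w = 1.0
            W[i, j] = W[j, i] = w

    return SnvNetwork(snv_ids=snv_ids, classes=classes, genes=genes, W=W)


def laplacian(network: SnvNetwork, normalized: bool = False) -> np.ndarray:
    """Graph Laplacian of the SNV network.

    Basic: L = D − W (row sums exactly zero).  Normalized:
    L = I − D^(−1/2) W D^(−1/2), where zero-degree nodes contribute
    identity rows (their D^(−1/2) entry is taken as 0), keeping L
    symmetric positive semidefinite.
    """
    W = network.W
    d = network.degree
    if not normalized:
        return np.diag(d) - W
    with np.errstate(divide="ignore"):
        dinv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    Q = (dinv[:, None] * W) * dinv[None, :]
    return np.eye(W.shape[0]) - Q


def laplacian_split(network: SnvNetwork, normalized: bool = False):
    """Split L = L_pos − L_neg with both parts entrywise non-negative.

    Basic Laplacian: (D, W).  Normalized: (I, D^(−1/2) W D^(−1/2)).
    The multiplicative update rules consume this split directly.  Both
    parts are returned as scipy sparse matrices: the SNV network is block
    sparse (within-gene cliques plus a handful of cross-gene edges), and
    the solver's per-iteration cost depends on it.
    """
    from scipy import sparse

    W = network.W
    d = network.degree
    if not normalized:
        return sparse.dia_matrix((d[None, :], [0]), shape=W.shape).tocsr(), sparse.csr_matrix(W)
    with np.errstate(divide="ignore"):
        dinv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    Q = (dinv[:, None] * W) * dinv[None, :]
    return sparse.identity(W.shape[0], format="csr"), sparse.csr_matrix(Q)
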