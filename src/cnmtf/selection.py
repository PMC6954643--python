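"""Grid-search selection of the rank k₁ and the penalty weights γ₁, γ₂, γ₃.

Selection is sequential: k₁ first (cluster stability via the dispersion
coefficient of the SNV consensus), then γ₁ (recall of known-association
genes among the prioritized set), then (γ₂, γ₃) jointly (case–control
separation of the consensus subject clusters).  All searches are
deterministic given the master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .factorization import PenaltyWeights, fit_consensus
from .scoring import assign_significance, permutation_null


@dataclass
class GridResult:
    parameter: str
    grid: list
    metric: list
    chosen: object
    criterion: str


def select_k1(
    prep,
    gammas: PenaltyWeights,
    k1_grid=range(2, 9),
    n_restarts: int = 10,
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int = 0,
) -> GridResult:
    """Choose k₁ maximizing the dispersion of the SNV consensus.

    For each candidate rank the model is refit over random restarts and
    the stability of the hard SNV clustering (row-argmax of U) across
    restarts is summarized by the dispersion coefficient; the most stable
    rank wins, ties going to the smaller (more parsimonious) rank.

    The exploration fits run at the symmetric rank k₂ = k₁: with the
    case-control k₂ = 2 the reconstruction U S Vᵀ has rank ≤ 2 and SNV
    clusterings beyond two groups are not identifiable, so rank structure
    is probed on the unconstrained factorization and only the final model
    is fit at k₂ = 2.  The phenotype term is therefore dropped here (Vo
    has two columns); the network and ancestry penalties still apply.
    """
    grid = [int(k) for k in k1_grid]
    if any(k < 2 for k in grid):
        raise ValueError("k1 grid values must be >= 2")
    if len(grid) == 1:
        warnings.warn("degenerate k1 grid of one value")
    metric: list[float] = []
    failures = 0
    for i, k1 in enumerate(grid):
        try:
            res = fit_consensus(
                prep.R,
                prep.L_pos,
                prep.L_neg,
                None,
                prep.HAH,
                PenaltyWeights(gammas.gamma1, 0.0, gammas.gamma3),
                k1=k1,
                k2=k1,
                n_restarts=n_restarts,
                tol=tol,
                max_iter=max_iter,
                seed=seed + i,
            )
            metric.append(res.snv_dispersion)
        except RuntimeError:
            failures += 1
            metric.append(-np.inf)
    if failures == len(grid):
        raise RuntimeError("every k1 fit was degenerate")
    best = max(range(len(grid)), key=lambda i: (metric[i], -grid[i]))
    return GridResult(
        parameter="k1",
        grid=grid,
        metric=metric,
        chosen=grid[best],
        criterion="max SNV-consensus dispersion (tie -> smaller k1)",
    )


def select_gamma1(
    prep,
    gammas_base: PenaltyWeights,
    gamma1_grid=(0.0, 1.0, 10.0, 100.0),
    k1: int = 4,
    n_restarts: int = 5,
    n_perm: int = 50,
    tol: float = 1e-4,
    max_iter: int = 150,
    seed: int = 0,
    alpha: float = 0.01,
) -> GridResult:
    """Choose γ₁ maximizing recall of known loci.

    Each grid point runs the fit plus a reduced permutation null and
    counts the prioritized SNVs that fall in known-association genes.
    γ₁ = 0 is the network-free baseline and should always be in the
    grid.  Ties go to the smaller γ₁.
    """
    if not prep.known_genes:
        raise ValueError("gamma1 selection needs known-association genes")
    grid = [float(g) for g in gamma1_grid]
    genes = prep.genes
    known = set(prep.known_genes)
    metric: list[float] = []
    for i, g1 in enumerate(grid):
        g = PenaltyWeights(g1, gammas_base.gamma2, gammas_base.gamma3)
        res = fit_consensus(
            prep.R, prep.L_pos, prep.L_neg, prep.Vo, prep.HAH, g,
            k1=k1, n_restarts=n_restarts, tol=tol, max_iter=max_iter, seed=seed + i,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null = permutation_null(
                prep.R, prep.labels, prep.L_pos, prep.L_neg, prep.HAH, g,
                k1=k1, n_perm=n_perm, n_restarts=min(n_restarts, 3),
                tol=tol, max_iter=max_iter, seed=seed + 1000 + i, alpha=alpha,
            )
        sig = assign_significance(res.mean_delta, null)
        in_known = np.isin(genes, list(known))
        metric.append(float((sig["prioritized"].to_numpy() & in_known).sum()))
    best = max(range(len(grid)), key=lambda i: (metric[i], -grid[i]))
    return GridResult(
        parameter="gamma1",
        grid=grid,
        metric=metric,
        chosen=grid[best],
        criterion="max count of prioritized SNVs in known genes (tie -> smaller gamma1)",
    )


def separation_metric(subject_clusters: np.ndarray, labels) -> float:
    """Majority-aligned fraction of subjects whose cluster matches their label.

    Clusters are relabelled by majority vote against the case/control
    labels, so the metric is at least 0.5 for two balanced clusters and 1
    for perfect separation.
    """
    labels = np.asarray(labels)
    y = (labels == "case").astype(int)
    acc = 0
    for c in np.unique(subject_clusters):
        members = subject_clusters == c
        acc += max(y[members].sum(), (1 - y[members]).sum())
    return acc / len(y)


def select_gamma23(
    prep,
    gammas_base: PenaltyWeights,
    gamma2_grid,
    gamma3_grid,
    k1: int = 4,
    n_restarts: int = 5,
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int = 0,
) -> tuple[GridResult, GridResult]:
    """Choose (γ₂, γ₃) maximizing case–control separation of the clusters.

    The Cartesian product of the two grids is searched; ties go first to
    the smaller γ₃, then the smaller γ₂ (prefer the least-regularized
    model among equally separating ones).
    """
    g2s = [float(g) for g in gamma2_grid]
    g3s = [float(g) for g in gamma3_grid]
    if not g2s or not g3s:
        raise ValueError("empty gamma grid")
    pairs = [(g2, g3) for g2 in g2s for g3 in g3s]
    metric: list[float] = []
    for i, (g2, g3) in enumerate(pairs):
        g = PenaltyWeights(gammas_base.gamma1, g2, g3)
        res = fit_consensus(
            prep.R, prep.L_pos, prep.L_neg, prep.Vo, prep.HAH, g,
            k1=k1, n_restarts=n_restarts, tol=tol, max_iter=max_iter, seed=seed + i,
        )
        metric.append(separation_metric(res.subject_clusters, prep.labels))
    best = max(range(len(pairs)), key=lambda i: (metric[i], -pairs[i][1], -pairs[i][0]))
    g2_best, g3_best = pairs[best]
    crit = "max case-control separation (tie -> smaller gamma3, then gamma2)"
    rep2 = GridResult("gamma2", g2s, [m for (g2, _), m in zip(pairs, metric) if True], g2_best, crit)
    rep3 = GridResult("gamma3", g3s, list(metric), g3_best, crit)
    rep2.metric = list(metric)
    rep2.grid = [list(p) for p in pairs]
    rep3.grid = [list(p) for p in pairs]
    return rep2, rep3
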