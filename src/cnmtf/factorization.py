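"""Penalized non-negative matrix tri-factorization with multiplicative updates.

The objective minimized here is

    J(U, S, V) = ||R - U S Vᵀ||²_F
               + γ₁ · tr(Uᵀ L U)
               + γ₂ · ||V - Vo||²_F
               + γ₃ · tr(V Vᵀ H A H)

with U (n×k₁), S (k₁×k₂), V (m×k₂) all element-wise non-negative.  L is a
graph Laplacian on the SNVs, Vo a one-hot phenotype matrix, and H A H a
doubly-centered ancestry kernel whose trace term is an HSIC penalty that
pushes the subject clustering V away from the population structure.

The solver is of the Lee–Seung / Ding multiplicative family: each partial
gradient is split into its positive and negative parts and the factor is
rescaled by their ratio, which preserves non-negativity.  The objective is
non-increasing under these updates in practice; monotone descent is
asserted by the test suite rather than assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

EPS = 1e-10  # denominator guard for multiplicative updates


@dataclass
class PenaltyWeights:
    """Weights of the three penalty terms.

    gamma1 : weight of the SNV-network Laplacian term (smooths U over edges)
    gamma2 : weight of the phenotype term (pulls V toward the one-hot Vo)
    gamma3 : weight of the ancestry HSIC term (decorrelates V from ancestry)

    All weights must be >= 0; all zero reduces the model to plain NMTF.
    """

    gamma1: float = 0.0
    gamma2: float = 0.0
    gamma3: float = 0.0

    def __post_init__(self) -> None:
        if min(self.gamma1, self.gamma2, self.gamma3) < 0:
            raise ValueError("penalty weights must be non-negative")


@dataclass
class FactorSet:
    """Non-negative factors of R ≈ U S Vᵀ.

    U (n×k₁) and V (m×k₂) act as cluster-indicator matrices for SNVs and
    subjects; S (k₁×k₂) links SNV clusters to subject clusters.
    """

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        n, k1 = self.U.shape
        k1s, k2 = self.S.shape
        m, k2v = self.V.shape
        if k1 != k1s or k2 != k2v:
            raise ValueError(
                f"inconsistent factor shapes U{self.U.shape} S{self.S.shape} V{self.V.shape}"
            )

    def reconstruction(self) -> np.ndarray:
        return self.U @ (self.S @ self.V.T)

    def copy(self) -> "FactorSet":
        return FactorSet(self.U.copy(), self.S.copy(), self.V.copy())


@dataclass
class ConsensusResult:
    """Consensus over random restarts of the factorization.

    consensus_matrix : m×m co-clustering frequency of subject pairs
    dispersion : stability of the subject consensus in [0, 1]
    snv_consensus_matrix : n×n co-clustering frequency of SNV pairs
    snv_dispersion : stability of the SNV consensus (used to choose k₁)
    mean_delta : per-SNV ΔΩ averaged across restarts (None if Vo absent)
    per_restart_objectives : final objective value of each restart
    subject_clusters : hard subject labels from the consensus matrix
    best_factors : factors of the restart with the lowest objective
    n_restarts_used : restarts that converged to a non-degenerate solution
    """

    consensus_matrix: np.ndarray
    dispersion: float
    snv_consensus_matrix: np.ndarray
    snv_dispersion: float
    mean_delta: np.ndarray | None
    per_restart_objectives: list[float]
    subject_clusters: np.ndarray
    best_factors: FactorSet
    n_restarts_used: int
    n_restarts_degenerate: int = 0
    restart_deltas: np.ndarray | None = None
    control_cluster: int | None = None
    case_cluster: int | None = None


def build_phenotype_matrix(labels) -> np.ndarray:
    """One-hot phenotype matrix Vo (m×2): column 0 controls, column 1 cases.

    ``labels`` is a sequence of "control"/"case" strings (or 0/1 integers).
    Subjects with any other label must be removed beforehand.
    """
    labels = np.asarray(labels)
    if labels.dtype.kind in "iub":
        codes = labels.astype(int)
        bad = ~np.isin(codes, [0, 1])
    else:
        lab = np.char.lower(labels.astype(str))
        codes = np.where(lab == "case", 1, 0)
        bad = ~np.isin(lab, ["control", "case"])
    if bad.any():
        raise ValueError(f"unknown phenotype labels at positions {np.flatnonzero(bad)[:10]}")
    m = len(codes)
    Vo = np.zeros((m, 2))
    Vo[np.arange(m), codes] = 1.0
    return Vo


def objective(
    R: np.ndarray,
    factors: FactorSet,
    L: np.ndarray | None = None,
    Vo: np.ndarray | None = None,
    HAH: np.ndarray | None = None,
    gammas: PenaltyWeights | None = None,
) -> float:
    """Evaluate the penalized tri-factorization objective J(U, S, V)."""
    g = gammas or PenaltyWeights()
    U, S, V = factors.U, factors.S, factors.V
    E = R - U @ (S @ V.T)
    value = float(np.vdot(E, E))
    if g.gamma1 > 0 and L is not None:
        value += g.gamma1 * float(np.vdot(U, L @ U))
    if g.gamma2 > 0 and Vo is not None:
        D = V - Vo
        value += g.gamma2 * float(np.vdot(D, D))
    if g.gamma3 > 0 and HAH is not None:
        value += g.gamma3 * float(np.vdot(V, HAH @ V))
    return value


def split_signed(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split M element-wise into (positive part, negative part), M = P − N."""
    P = np.maximum(M, 0.0)
    N = np.maximum(-M, 0.0)
    return P, N


def update_step(
    R: np.ndarray,
    factors: FactorSet,
    L_pos: np.ndarray | None = None,
    L_neg: np.ndarray | None = None,
    Vo: np.ndarray | None = None,
    HAH_pos: np.ndarray | None = None,
    HAH_neg: np.ndarray | None = None,
    gammas: PenaltyWeights | None = None,
    eps: float = EPS,
) -> FactorSet:
    """One multiplicative pass over U, S, V (in place on copies).

    ``L_pos``/``L_neg`` is the Laplacian split L = L_pos − L_neg with both
    parts entrywise non-negative (basic: D and W; normalized: I and
    D^-1/2 W D^-1/2).  ``HAH_pos``/``HAH_neg`` is the element-wise split of
    the centered ancestry kernel.  Each factor update uses the already
    updated factors before it, which keeps every block update a descent
    step on the current objective.
    """
    g = gammas or PenaltyWeights()
    U, S, V = factors.U.copy(), factors.S.copy(), factors.V.copy()

    # --- U ---------------------------------------------------------------
    VtV = V.T @ V
    num = R @ (V @ S.T)
    den = U @ (S @ VtV @ S.T)
    if g.gamma1 > 0 and L_neg is not None:
        num += g.gamma1 * (L_neg @ U)
        den += g.gamma1 * (L_pos @ U)
    U *= num / (den + eps)

    # --- S ---------------------------------------------------------------
    UtU = U.T @ U
    num = U.T @ (R @ V)
    den = UtU @ S @ VtV
    S *= num / (den + eps)

    # --- V ---------------------------------------------------------------
    US = U @ S
    num = R.T @ US
    den = V @ (S.T @ UtU @ S)
    if g.gamma2 > 0 and Vo is not None:
        num = num + g.gamma2 * Vo
        den = den + g.gamma2 * V
    if g.gamma3 > 0 and HAH_pos is not None:
        num = num + g.gamma3 * (HAH_neg @ V)
        den = den + g.gamma3 * (HAH_pos @ V)
    V *= num / (den + eps)

    out = FactorSet(U, S, V)
    if not (
        np.isfinite(U).all() and np.isfinite(S).all() and np.isfinite(V).all()
    ):
        raise FloatingPointError(
            "non-finite factor entries after multiplicative update "
            f"(|U|max={np.nanmax(np.abs(U)):.3g}, |S|max={np.nanmax(np.abs(S)):.3g}, "
            f"|V|max={np.nanmax(np.abs(V)):.3g})"
        )
    return out


def _init_factors(n: int, m: int, k1: int, k2: int, rng: np.random.Generator) -> FactorSet:
    # strictly positive start: multiplicative updates cannot leave zeros
    return FactorSet(
        U=rng.uniform(0.1, 1.1, size=(n, k1)),
        S=rng.uniform(0.1, 1.1, size=(k1, k2)),
        V=rng.uniform(0.1, 1.1, size=(m, k2)),
    )


def _rejitter_empty_columns(fac: FactorSet, rng: np.random.Generator) -> bool:
    """Re-seed any factor column that collapsed to ~0.  Returns True if any did."""
    hit = False
    for M in (fac.U, fac.V):
        col_max = M.max(axis=0)
        for j in np.flatnonzero(col_max < 1e-12):
            M[:, j] = rng.uniform(0.1, 1.1, size=M.shape[0])
            hit = True
    return hit


def fit_once(
    R: np.ndarray,
    L_pos=None,
    L_neg=None,
    Vo: np.ndarray | None = None,
    HAH: np.ndarray | None = None,
    gammas: PenaltyWeights | None = None,
    k1: int = 4,
    k2: int = 2,
    tol: float = 1e-5,
    max_iter: int = 500,
    seed: int | np.random.Generator = 0,
) -> tuple[FactorSet, np.ndarray, bool]:
    """Run multiplicative updates from one random start.

    Returns (factors, objective trace, converged flag).  The trace includes
    the objective at initialization, so ``len(trace) == n_iterations + 1``.
    Iteration stops when the relative objective change drops below ``tol``
    or after ``max_iter`` passes (warning flag, not an error).

    ``L_pos``/``L_neg`` may be dense arrays or scipy sparse matrices; the
    network split is typically very sparse (within-gene blocks plus a few
    cross-gene edges), which keeps the per-iteration cost at
    O(n·m·k + m²·k) regardless of n².  The objective trace is evaluated
    from the same intermediates the updates consume, so tracing adds
    almost nothing on top of the updates themselves.
    """
    g = gammas or PenaltyWeights()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, m = R.shape
    fac = _init_factors(n, m, k1, k2, rng)
    U, S, V = fac.U, fac.S, fac.V

    use_net = g.gamma1 > 0 and L_pos is not None
    use_phen = g.gamma2 > 0 and Vo is not None
    use_anc = g.gamma3 > 0 and HAH is not None
    HAH_pos = HAH_neg = None
    if use_anc:
        HAH_pos, HAH_neg = split_signed(np.asarray(HAH))
    R2 = float(np.vdot(R, R))

    trace: list[float] = []
    converged = False
    rejittered = False
    it = 0
    while True:
        # ---- intermediates of the CURRENT factors -----------------------
        VtV = V.T @ V
        RV = R @ V  # n×k2, reused by the objective and the U update
        US = U @ S
        LpU = L_pos @ U if use_net else None
        LnU = L_neg @ U if use_net else None
        HpV = HAH_pos @ V if use_anc else None
        HnV = HAH_neg @ V if use_anc else None
        UtU = U.T @ U

        j = R2 - 2.0 * float(np.vdot(RV, US)) + float(np.vdot(S.T @ UtU @ S, VtV))
        if use_net:
            j += g.gamma1 * (float(np.vdot(U, LpU)) - float(np.vdot(U, LnU)))
        if use_phen:
            Dv = V - Vo
            j += g.gamma2 * float(np.vdot(Dv, Dv))
        if use_anc:
            j += g.gamma3 * (float(np.vdot(V, HpV)) - float(np.vdot(V, HnV)))
        trace.append(j)

        if it > 0:
            prev = trace[-2]
            if abs(prev - j) <= tol * max(abs(prev), 1e-30):
                converged = True
                break
        if it >= max_iter:
            break
        it += 1

        # ---- U ----------------------------------------------------------
        num = RV @ S.T
        den = U @ (S @ VtV @ S.T)
        if use_net:
            num = num + g.gamma1 * LnU
            den = den + g.gamma1 * LpU
        U *= num / (den + EPS)

        # ---- S (with the updated U; V unchanged, so RV is still valid) --
        UtU = U.T @ U
        num = U.T @ RV
        den = UtU @ S @ VtV
        S *= num / (den + EPS)

        # ---- V ----------------------------------------------------------
        US = U @ S
        num = R.T @ US
        den = V @ (S.T @ UtU @ S)
        if use_phen:
            num = num + g.gamma2 * Vo
            den = den + g.gamma2 * V
        if use_anc:
            num = num + g.gamma3 * HnV
            den = den + g.gamma3 * HpV
        V *= num / (den + EPS)

        if not (np.isfinite(U).all() and np.isfinite(S).all() and np.isfinite(V).all()):
            raise FloatingPointError(
                f"non-finite factors at iteration {it} "
                f"(|U|max={np.nanmax(np.abs(U)):.3g}, |V|max={np.nanmax(np.abs(V)):.3g})"
            )
        if _rejitter_empty_columns(fac, rng):
            if rejittered:
                warnings.warn("factor column collapsed twice; marking restart degenerate")
                return fac, np.asarray(trace), False
            rejittered = True
            warnings.warn("empty factor column re-jittered")
        # tol = inf stops at the next top-of-loop check: exactly one iteration
    return fac, np.asarray(trace), converged


def dispersion(consensus: np.ndarray) -> float:
    """Dispersion coefficient ρ = (1/m²)·Σ 4(C_ij − ½)² of a consensus matrix.

    ρ = 1 when every pair of items is either always or never co-clustered
    across restarts (perfectly stable clustering); ρ = 0 when every pair is
    co-clustered in exactly half of the restarts (maximal ambiguity).
    """
    C = np.asarray(consensus, dtype=float)
    return float(np.mean(4.0 * (C - 0.5) ** 2))


def _consensus_from_labels(labels: np.ndarray) -> np.ndarray:
    """Co-clustering frequency matrix from an (n_restarts × m) label array."""
    r = labels.shape[0]
    C = np.zeros((labels.shape[1], labels.shape[1]))
    for row in labels:
        C += row[:, None] == row[None, :]
    return C / r


def fit_consensus(
    R: np.ndarray,
    L_pos: np.ndarray | None = None,
    L_neg: np.ndarray | None = None,
    Vo: np.ndarray | None = None,
    HAH: np.ndarray | None = None,
    gammas: PenaltyWeights | None = None,
    k1: int = 4,
    k2: int = 2,
    n_restarts: int = 10,
    tol: float = 1e-5,
    max_iter: int = 500,
    seed: int = 0,
    combine: str = "mean",
) -> ConsensusResult:
    """Fit with ``n_restarts`` random initializations and build a consensus.

    Each restart yields hard subject clusters (row-argmax of V), hard SNV
    clusters (row-argmax of U) and, when ``Vo`` is supplied, a ΔΩ vector
    oriented by matching the V columns to the Vo label columns.  The
    consensus matrix is the co-clustering frequency over non-degenerate
    restarts; final subject clusters come from average-linkage hierarchical
    clustering of ``1 − consensus``; ΔΩ is combined across restarts by
    ``combine`` ("mean" or "median").
    """
    from .scoring import map_clusters, snv_scores, delta_scores

    if n_restarts < 2:
        raise ValueError("consensus requires n_restarts >= 2")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_restarts)

    subj_labels, snv_labels, objs, deltas = [], [], [], []
    best: FactorSet | None = None
    best_obj = np.inf
    n_degenerate = 0
    for cs in child_seeds:
        rng = np.random.default_rng(cs)
        fac, trace, _ = fit_once(
            R, L_pos, L_neg, Vo, HAH, gammas, k1, k2, tol, max_iter, seed=rng
        )
        delta = None
        if Vo is not None:
            try:
                ctrl, case = map_clusters(fac.V, Vo)
                delta = delta_scores(snv_scores(fac.U, fac.S), ctrl, case)
            except ValueError:
                n_degenerate += 1
                continue
        subj_labels.append(np.argmax(fac.V, axis=1))
        snv_labels.append(np.argmax(fac.U, axis=1))
        objs.append(float(trace[-1]))
        if delta is not None:
            deltas.append(delta)
        if trace[-1] < best_obj:
            best_obj = float(trace[-1])
            best = fac
    if n_degenerate:
        warnings.warn(f"{n_degenerate} degenerate restart(s) excluded from consensus")
    if len(subj_labels) < 2:
        raise RuntimeError("fewer than two non-degenerate restarts; cannot build consensus")

    C_subj = _consensus_from_labels(np.asarray(subj_labels))
    C_snv = _consensus_from_labels(np.asarray(snv_labels))

    from scipy.cluster.hierarchy import average, fcluster
    from scipy.spatial.distance import squareform

    Dmat = 1.0 - C_subj
    np.fill_diagonal(Dmat, 0.0)
    link = average(squareform(Dmat, checks=False))
    subject_clusters = fcluster(link, t=k2, criterion="maxclust") - 1

    restart_deltas = np.asarray(deltas) if deltas else None
    if restart_deltas is not None:
        mean_delta = (
            np.median(restart_deltas, axis=0)
            if combine == "median"
            else restart_deltas.mean(axis=0)
        )
    else:
        mean_delta = None

    ctrl = case = None
    if Vo is not None and best is not None:
        try:
            ctrl, case = map_clusters(best.V, Vo)
        except ValueError:
            pass

    return ConsensusResult(
        consensus_matrix=C_subj,
        dispersion=dispersion(C_subj),
        snv_consensus_matrix=C_snv,
        snv_dispersion=dispersion(C_snv),
        mean_delta=mean_delta,
        per_restart_objectives=objs,
        subject_clusters=subject_clusters,
        best_factors=best,
        n_restarts_used=len(subj_labels),
        n_restarts_degenerate=n_degenerate,
        restart_deltas=restart_deltas,
        control_cluster=ctrl,
        case_cluster=case,
    )
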