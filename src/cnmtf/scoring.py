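"""SNV scores, delta scores, permutation null and gene ranking.

The factorization summarizes each variant's importance to each subject
cluster in the score matrix Ω = U·S.  The delta score

    ΔΩ_s = Ω[s, controls] − Ω[s, cases]

captures the net effect of the recessive allele: positive ΔΩ means the
allele is over-represented in the control cluster (protective trend),
negative means detrimental.  Significance is empirical: the phenotype
labels are permuted, the whole fit is re-run, and the ΔΩ values of all
SNVs across all permutations are pooled into one null distribution whose
(α/2, 1−α/2) quantiles give the prioritization cutoffs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .factorization import PenaltyWeights, build_phenotype_matrix, fit_consensus


def snv_scores(U: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Score matrix Ω = U·S (n SNVs × k₂ subject clusters), entrywise ≥ 0."""
    return np.asarray(U) @ np.asarray(S)


def delta_scores(omega: np.ndarray, control_cluster: int, case_cluster: int) -> np.ndarray:
    """ΔΩ_s = Ω[s, controls] − Ω[s, cases]; positive = protective trend."""
    if control_cluster == case_cluster:
        raise ValueError("control and case cluster indices must differ")
    omega = np.asarray(omega)
    return omega[:, control_cluster] - omega[:, case_cluster]


def map_clusters(V: np.ndarray, Vo: np.ndarray) -> tuple[int, int]:
    """Identify which fitted V column is the control cluster.

    Subjects are hard-assigned by row-argmax of V and of Vo; the V column
    whose members are most enriched in Vo controls becomes the control
    cluster.  A tie means the fit did not separate the phenotype and the
    caller should re-run with a different seed or stronger γ₂.
    """
    V = np.asarray(V)
    Vo = np.asarray(Vo)
    if V.shape != Vo.shape:
        raise ValueError("V and Vo shape mismatch")
    assign = np.argmax(V, axis=1)
    truth = np.argmax(Vo, axis=1)
    k = V.shape[1]
    # overlap[l, c] = # subjects in fitted cluster l with true label c
    overlap = np.zeros((k, k), dtype=int)
    np.add.at(overlap, (assign, truth), 1)
    ctrl_scores = overlap[:, 0].astype(float)
    # normalize by cluster size so a giant mixed cluster does not win
    sizes = overlap.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(sizes > 0, ctrl_scores / np.maximum(sizes, 1), -1.0)
    order = np.argsort(-frac, kind="stable")
    if frac[order[0]] == frac[order[1]]:
        raise ValueError(
            "degenerate fit: control enrichment tied between clusters; re-run"
        )
    control = int(order[0])
    case = int(order[1]) if k == 2 else int(np.argmin(frac))
    return control, case


@dataclass
class NullDistribution:
    """Pooled empirical null of ΔΩ under phenotype permutation.

    cutoff_low/cutoff_high are the empirical (α/2, 1−α/2) quantiles of the
    pooled null; an observed ΔΩ outside [cutoff_low, cutoff_high] is
    prioritized.
    """

    samples: np.ndarray
    n_permutations: int
    alpha: float
    cutoff_low: float
    cutoff_high: float

    @classmethod
    def from_samples(
        cls, samples: np.ndarray, n_permutations: int, alpha: float = 0.01
    ) -> "NullDistribution":
        samples = np.asarray(samples, dtype=float).ravel()
        if samples.size == 0:
            raise ValueError("empty null distribution")
        lo, hi = np.quantile(samples, [alpha / 2.0, 1.0 - alpha / 2.0])
        return cls(
            samples=samples,
            n_permutations=n_permutations,
            alpha=alpha,
            cutoff_low=float(lo),
            cutoff_high=float(hi),
        )


def permutation_samples(
    R: np.ndarray,
    labels,
    L_pos: np.ndarray | None = None,
    L_neg: np.ndarray | None = None,
    HAH: np.ndarray | None = None,
    gammas: PenaltyWeights | None = None,
    k1: int = 4,
    k2: int = 2,
    n_perm: int = 1000,
    n_restarts: int = 5,
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int = 0,
    start: int = 0,
):
    """Yield (permutation index, mean ΔΩ vector | None) for each permutation.

    Each permutation index gets its own seed stream spawned from the
    master seed, so a run can be resumed from ``start`` and reproduces
    the same draws regardless of where it was interrupted.  None is
    yielded when the permuted fit cannot be oriented against its labels.
    """
    labels = np.asarray(labels)
    children = np.random.SeedSequence(seed).spawn(n_perm)
    for p in range(start, n_perm):
        rng_p = np.random.default_rng(children[p])
        perm = rng_p.permutation(labels)
        Vo = build_phenotype_matrix(perm)
        try:
            res = fit_consensus(
                R,
                L_pos,
                L_neg,
                Vo,
                HAH,
                gammas,
                k1=k1,
                k2=k2,
                n_restarts=n_restarts,
                tol=tol,
                max_iter=max_iter,
                seed=int(rng_p.integers(2**31 - 1)),
            )
            yield p, res.mean_delta
        except (RuntimeError, ValueError):
            yield p, None


def permutation_null(
    R: np.ndarray,
    labels,
    L_pos: np.ndarray | None = None,
    L_neg: np.ndarray | None = None,
    HAH: np.ndarray | None = None,
    gammas: PenaltyWeights | None = None,
    k1: int = 4,
    k2: int = 2,
    n_perm: int = 1000,
    n_restarts: int = 5,
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int = 0,
    alpha: float = 0.01,
) -> NullDistribution:
    """Build the pooled ΔΩ null by re-fitting under permuted phenotypes.

    Each permutation shuffles the case/control labels (case count
    preserved), rebuilds Vo, runs a consensus fit and pools the mean ΔΩ of
    every SNV.  Permutations whose fit cannot be oriented (degenerate
    clustering) are dropped; more than 10% failures is an error.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; cutoff estimates will be noisy")
    pooled: list[np.ndarray] = []
    failures = 0
    for _, delta in permutation_samples(
        R, labels, L_pos, L_neg, HAH, gammas, k1, k2, n_perm,
        n_restarts, tol, max_iter, seed,
    ):
        if delta is None:
            failures += 1
        else:
            pooled.append(delta)
    if failures:
        warnings.warn(f"{failures}/{n_perm} permutations failed to orient and were dropped")
    if failures > 0.1 * n_perm:
        raise RuntimeError(f"{failures}/{n_perm} permutations failed (>10%)")
    samples = np.concatenate(pooled)
    return NullDistribution.from_samples(samples, n_permutations=n_perm - failures, alpha=alpha)


def assign_significance(delta: np.ndarray, null: NullDistribution) -> pd.DataFrame:
    """Empirical p-values and prioritization flags for observed ΔΩ.

    Two-sided p with add-one smoothing:
    p_s = (1 + #{|null| ≥ |ΔΩ_s|}) / (1 + #null).  Prioritization uses the
    asymmetric empirical quantile cutoffs, exactly as the null defines
    them.
    """
    delta = np.asarray(delta, dtype=float)
    abs_null = np.sort(np.abs(null.samples))
    n_null = abs_null.size
    # count of null values with |value| >= |delta_s|
    geq = n_null - np.searchsorted(abs_null, np.abs(delta), side="left")
    p = (1.0 + geq) / (1.0 + n_null)
    prioritized = (delta < null.cutoff_low) | (delta > null.cutoff_high)
    trend = np.where(delta > 0, "protective", "detrimental")
    return pd.DataFrame(
        {"delta": delta, "p_value": p, "prioritized": prioritized, "trend": trend}
    )


def score_table(
    snv_ids,
    genes,
    omega: np.ndarray,
    control_cluster: int,
    case_cluster: int,
    null: NullDistribution,
    classes=None,
    positions=None,
) -> pd.DataFrame:
    """Assemble the per-SNV prioritization table."""
    delta = delta_scores(omega, control_cluster, case_cluster)
    sig = assign_significance(delta, null)
    tab = pd.DataFrame(
        {
            "snv_id": list(snv_ids),
            "gene": list(genes),
            "omega_controls": omega[:, control_cluster],
            "omega_cases": omega[:, case_cluster],
        }
    )
    out = pd.concat([tab, sig.reset_index(drop=True)], axis=1)
    if classes is not None:
        out["class"] = list(classes)
    if positions is not None:
        out["position"] = list(positions)
    return out


def rank_genes(scores: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by their best (lowest-p) SNV.

    Ties on p are broken by larger |ΔΩ|, then lexicographic snv_id, so the
    ranking is deterministic.  Returns one row per gene sorted ascending
    by the representative p-value.
    """
    df = scores.copy()
    df["_abs_delta"] = df["delta"].abs()
    df = df.sort_values(
        ["gene", "p_value", "_abs_delta", "snv_id"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    best = df.groupby("gene", sort=False).head(1)
    n_snvs = df.groupby("gene", sort=False).size().rename("n_snvs")
    n_prior = (
        df.groupby("gene", sort=False)["prioritized"].any().rename("any_prioritized")
    )
    out = (
        best.set_index("gene")
        .join(n_snvs)
        .join(n_prior)
        .reset_index()
        .rename(columns={"snv_id": "best_snv", "p_value": "p"})
    )
    out = out[
        ["gene", "best_snv", "p", "delta", "trend", "prioritized", "any_prioritized", "n_snvs"]
    ]
    return out.sort_values(["p", "gene"], ascending=[True, True], kind="stable").reset_index(
        drop=True
    )
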