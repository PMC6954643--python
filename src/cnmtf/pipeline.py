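"""End-to-end orchestration: inputs → network/kernel → fit → null → scores.

``prepare_inputs`` aligns all data sources on shared identifiers and
precomputes the factorization inputs (Laplacian split, centered ancestry
kernel, one-hot phenotype matrix).  ``analyze`` runs the whole method on
prepared inputs; ``run_pipeline`` wraps it with file I/O and a manifest
for the command-line interface.

A note on penalty scales: the reconstruction term sums over n×m entries
while ``||V − Vo||²`` sums over m×k₂, so a γ₂ that competes with the data
term must be of order n.  When γ₂ or γ₃ is given as None the pipeline
materializes scale-aware defaults (γ₂ = n/2, γ₃ = n/2) rather than bare
constants; the manifest always records the resolved values.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .correction import AncestryKernel, ancestry_kernel
from .factorization import (
    ConsensusResult,
    PenaltyWeights,
    build_phenotype_matrix,
    fit_consensus,
)
from .network import SnvNetwork, build_snv_network, classify_variants, laplacian_split
from .preprocess import GenotypeMatrix, clump_ld, select_snv_subset
from .scoring import NullDistribution, assign_significance, permutation_null, rank_genes, snv_scores

log = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """All tunable parameters of a run, with materialized defaults.

    ``gamma1``/``gamma2``/``gamma3`` may be None (scale-aware default) or
    "auto" (grid search via the selection module).  ``k1`` may be an
    integer or "auto" (dispersion-maximizing grid search).
    """

    k1: int | str = 4
    k2: int = 2
    gamma1: float | str | None = 1.0
    gamma2: float | str | None = None
    gamma3: float | str | None = None
    n_restarts: int = 20
    tol: float = 1e-5
    max_iter: int = 300
    alpha: float = 0.01
    n_perm: int = 1000
    perm_restarts: int | None = None  # None: same as n_restarts (keeps null exchangeable)
    perm_max_iter: int | None = None
    n_pcs: int = 5
    normalized_laplacian: bool = False
    cross_gene_mode: str = "ppi"
    clump: bool = False
    r2_threshold: float = 0.5
    subset_to_seed_neighbourhood: bool = False
    combine: str = "mean"
    seed: int = 0


@dataclass
class PreparedInputs:
    """Aligned, precomputed inputs consumed by the solver and selectors."""

    R: np.ndarray
    snv_ids: list[str]
    subject_ids: list[str]
    labels: np.ndarray
    Vo: np.ndarray
    network: SnvNetwork
    L_pos: np.ndarray
    L_neg: np.ndarray
    kernel: AncestryKernel
    annotations: pd.DataFrame  # aligned to snv_ids order
    known_genes: list[str]
    proxy_map: dict = field(default_factory=dict)

    @property
    def HAH(self) -> np.ndarray:
        return self.kernel.centered_product

    @property
    def genes(self) -> np.ndarray:
        return np.asarray(self.annotations["gene"])


@dataclass
class AnalysisResult:
    scores: pd.DataFrame
    gene_table: pd.DataFrame
    null: NullDistribution
    consensus: ConsensusResult
    prepared: PreparedInputs
    gammas: PenaltyWeights
    k1: int
    selection_reports: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def resolve_gammas(params: PipelineParams, n: int) -> PenaltyWeights:
    """Materialize numeric penalty weights (scale-aware defaults for None)."""
    g1 = 1.0 if params.gamma1 is None else params.gamma1
    g2 = 0.5 * n if params.gamma2 is None else params.gamma2
    g3 = 0.5 * n if params.gamma3 is None else params.gamma3
    for name, g in (("gamma1", g1), ("gamma2", g2), ("gamma3", g3)):
        if isinstance(g, str):
            raise ValueError(f"{name}='auto' must be resolved by the selection step")
    return PenaltyWeights(float(g1), float(g2), float(g3))


def prepare_inputs(
    geno: GenotypeMatrix,
    labels,
    annotations: pd.DataFrame,
    ppi_edges,
    params: PipelineParams,
) -> PreparedInputs:
    """Align identifiers, apply subsetting/clumping, build network and kernel."""
    labels = np.asarray(labels)
    if len(labels) != len(geno.subject_ids):
        raise ValueError("label vector length does not match subject count")

    ann = annotations.copy()
    orphans = set(geno.snv_ids) - set(ann["snv_id"])
    if orphans:
        raise ValueError(f"SNVs missing from annotations: {sorted(orphans)[:10]}")

    # drop excluded subjects (intermediate trait band)
    keep = np.isin(labels, ["control", "case"])
    if not keep.all():
        geno = GenotypeMatrix(
            geno.values[:, keep],
            list(geno.snv_ids),
            [s for s, k in zip(geno.subject_ids, keep) if k],
        )
        labels = labels[keep]

    known_genes = sorted(set(ann.loc[ann["known_association"].astype(bool), "gene"]))

    if params.subset_to_seed_neighbourhood:
        if not known_genes:
            raise ValueError("subsetting requested but no known-association seed genes")
        snvs, _genes = select_snv_subset(known_genes, ppi_edges, ann)
        geno = geno.subset_snvs(snvs)
        ann = ann[ann["snv_id"].isin(snvs)]

    proxy_map: dict = {}
    if params.clump:
        res = clump_ld(geno, labels, ann, params.r2_threshold)
        geno, ann, proxy_map = res.genotypes, res.annotations, res.proxy_map

    ann = ann.set_index("snv_id").loc[geno.snv_ids].reset_index()
    classes = classify_variants(ann)
    net = build_snv_network(
        classes,
        list(ann["gene"]),
        ppi_edges,
        geno.snv_ids,
        cross_gene_mode=params.cross_gene_mode,
    )
    L_pos, L_neg = laplacian_split(net, normalized=params.normalized_laplacian)
    kernel = ancestry_kernel(geno.values.astype(float), n_pcs=params.n_pcs)
    Vo = build_phenotype_matrix(labels)
    return PreparedInputs(
        R=geno.values.astype(float),
        snv_ids=list(geno.snv_ids),
        subject_ids=list(geno.subject_ids),
        labels=labels,
        Vo=Vo,
        network=net,
        L_pos=L_pos,
        L_neg=L_neg,
        kernel=kernel,
        annotations=ann,
        known_genes=known_genes,
        proxy_map=proxy_map,
    )


def analyze(
    geno: GenotypeMatrix,
    labels,
    annotations: pd.DataFrame,
    ppi_edges,
    params: PipelineParams | None = None,
    **overrides,
) -> AnalysisResult:
    """Run the full method on in-memory inputs and return all artifacts."""
    from . import selection  # local import: selection drives this module's inputs

    params = params or PipelineParams()
    if overrides:
        params = PipelineParams(**{**asdict(params), **overrides})
    prep = prepare_inputs(geno, labels, annotations, ppi_edges, params)
    n = prep.R.shape[0]
    reports: dict = {}

    k1 = params.k1
    base = resolve_gammas(
        PipelineParams(
            **{
                **asdict(params),
                "gamma1": None if params.gamma1 == "auto" else params.gamma1,
                "gamma2": None if params.gamma2 == "auto" else params.gamma2,
                "gamma3": None if params.gamma3 == "auto" else params.gamma3,
            }
        ),
        n,
    )
    if k1 == "auto":
        rep = selection.select_k1(
            prep,
            base,
            k1_grid=range(2, 9),
            n_restarts=max(5, params.n_restarts // 4),
            tol=params.tol,
            max_iter=params.max_iter,
            seed=params.seed + 101,
        )
        k1 = rep.chosen
        reports["k1"] = rep
    k1 = int(k1)

    gammas = base
    if params.gamma1 == "auto":
        rep = selection.select_gamma1(
            prep,
            gammas,
            gamma1_grid=[0.0, 1.0, 10.0, 100.0],
            k1=k1,
            seed=params.seed + 202,
            alpha=params.alpha,
        )
        gammas = PenaltyWeights(float(rep.chosen), gammas.gamma2, gammas.gamma3)
        reports["gamma1"] = rep
    if params.gamma2 == "auto" or params.gamma3 == "auto":
        g2_grid = [0.0, 0.1 * n, 0.5 * n, 2.0 * n] if params.gamma2 == "auto" else [gammas.gamma2]
        g3_grid = [0.0, 0.1 * n, 0.5 * n, 2.0 * n] if params.gamma3 == "auto" else [gammas.gamma3]
        rep2, rep3 = selection.select_gamma23(
            prep,
            gammas,
            gamma2_grid=g2_grid,
            gamma3_grid=g3_grid,
            k1=k1,
            n_restarts=max(5, params.n_restarts // 4),
            tol=params.tol,
            max_iter=params.max_iter,
            seed=params.seed + 303,
        )
        gammas = PenaltyWeights(gammas.gamma1, float(rep2.chosen), float(rep3.chosen))
        reports["gamma2"], reports["gamma3"] = rep2, rep3

    t0 = time.time()
    consensus = fit_consensus(
        prep.R,
        prep.L_pos,
        prep.L_neg,
        prep.Vo,
        prep.HAH,
        gammas,
        k1=k1,
        k2=params.k2,
        n_restarts=params.n_restarts,
        tol=params.tol,
        max_iter=params.max_iter,
        seed=params.seed,
        combine=params.combine,
    )
    log.info("main consensus fit: %.1fs, dispersion %.3f", time.time() - t0, consensus.dispersion)

    t0 = time.time()
    null = permutation_null(
        prep.R,
        prep.labels,
        prep.L_pos,
        prep.L_neg,
        prep.HAH,
        gammas,
        k1=k1,
        k2=params.k2,
        n_perm=params.n_perm,
        n_restarts=params.perm_restarts or params.n_restarts,
        tol=params.tol,
        max_iter=params.perm_max_iter or params.max_iter,
        seed=params.seed + 7919,
        alpha=params.alpha,
    )
    log.info("permutation null: %.1fs, cutoffs (%.3g, %.3g)", time.time() - t0,
             null.cutoff_low, null.cutoff_high)

    fac = consensus.best_factors
    omega = snv_scores(fac.U, fac.S)
    ctrl, case = consensus.control_cluster, consensus.case_cluster
    if ctrl is None:
        raise RuntimeError("main fit could not be oriented against the phenotype")
    delta = consensus.mean_delta
    sig = assign_significance(delta, null)
    scores = pd.DataFrame(
        {
            "snv_id": prep.snv_ids,
            "gene": prep.genes,
            "position": prep.annotations["position"].to_numpy(),
            "class": prep.network.classes,
            "omega_controls": omega[:, ctrl],
            "omega_cases": omega[:, case],
        }
    )
    scores = pd.concat([scores, sig.reset_index(drop=True)], axis=1)
    gene_table = rank_genes(scores)

    manifest = {
        "params": {k: (v if not isinstance(v, (np.floating, np.integer)) else float(v))
                   for k, v in asdict(params).items()},
        "resolved": {
            "k1": k1,
            "gamma1": gammas.gamma1,
            "gamma2": gammas.gamma2,
            "gamma3": gammas.gamma3,
            "n_snvs": n,
            "n_subjects": prep.R.shape[1],
            "n_controls": int((prep.labels == "control").sum()),
            "n_cases": int((prep.labels == "case").sum()),
            "null_cutoff_low": null.cutoff_low,
            "null_cutoff_high": null.cutoff_high,
            "dispersion": consensus.dispersion,
        },
    }
    return AnalysisResult(
        scores=scores,
        gene_table=gene_table,
        null=null,
        consensus=consensus,
        prepared=prep,
        gammas=gammas,
        k1=k1,
        selection_reports=reports,
        manifest=manifest,
    )


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(
    genotype_path: str | Path,
    phenotype_path: str | Path,
    annotation_path: str | Path,
    ppi_path: str | Path,
    out_dir: str | Path,
    params: PipelineParams | None = None,
    trait_column: str | None = None,
    label_column: str = "label",
    covariate_columns: tuple[str, ...] = (),
    control_cutoff: float | None = None,
    case_cutoff: float | None = None,
    orientation: str = "low_is_control",
) -> AnalysisResult:
    """File-based front end: read inputs, analyze, write output tables.

    Phenotypes may arrive pre-categorized (``label_column``) or as a
    continuous trait plus cutoffs (``trait_column``/cutoffs), in which
    case the trait is residualized on the covariates and categorized.
    """
    from . import io as cio
    from .preprocess import categorize_phenotype, residualize_trait

    params = params or PipelineParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    geno = cio.read_genotypes(genotype_path)
    phen = cio.read_phenotypes(phenotype_path)
    ann = cio.read_annotations(annotation_path)
    ppi = cio.read_ppi(ppi_path)

    orphan_subj = set(geno.subject_ids) ^ set(phen["subject_id"])
    if orphan_subj:
        raise ValueError(
            f"subject identifiers differ between genotypes and phenotypes: {sorted(orphan_subj)[:10]}"
        )
    phen = phen.set_index("subject_id").loc[geno.subject_ids].reset_index()

    if trait_column is not None:
        if control_cutoff is None or case_cutoff is None:
            raise ValueError("trait categorization requires both cutoffs")
        values = phen[trait_column].to_numpy(dtype=float)
        if covariate_columns:
            corrected = residualize_trait(values, phen[list(covariate_columns)])
            values = corrected + values.mean()  # keep cutoffs on the original scale
        labels = categorize_phenotype(values, control_cutoff, case_cutoff, orientation)
    else:
        labels = phen[label_column].to_numpy()

    result = analyze(geno, labels, ann, ppi, params)

    result.scores.to_csv(out / "snv_scores.tsv", sep="\t", index=False)
    result.gene_table.to_csv(out / "gene_ranking.tsv", sep="\t", index=False)
    np.savetxt(out / "null_samples.tsv.gz", result.null.samples, fmt="%.6g")
    pd.DataFrame(result.consensus.consensus_matrix).to_csv(
        out / "consensus_matrix.tsv", sep="\t", index=False, header=False,
        float_format="%.4f",
    )
    manifest = dict(result.manifest)
    manifest["inputs"] = {
        str(p): _hash_file(Path(p))
        for p in (genotype_path, phenotype_path, annotation_path, ppi_path)
    }
    manifest["selection"] = {
        name: {"grid": list(map(float, rep.grid)), "metric": list(map(float, rep.metric)),
               "chosen": float(rep.chosen), "criterion": rep.criterion}
        for name, rep in result.selection_reports.items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    result.manifest = manifest
    return result
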