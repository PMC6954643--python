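"""Phenotype categorization, confounder residualization, SNV subsetting, LD clumping.

These steps turn raw genotype/phenotype/annotation tables into the inputs
the factorization consumes: case/control labels from trait cutoffs (the
intermediate band is excluded), a confounder-corrected trait, the SNV
universe restricted to seed genes and their first PPI neighbourhood, and
an LD-clumped genotype matrix where each high-LD group within a gene is
represented by its most trait-associated proxy variant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Additive-coded genotypes: n SNVs × m subjects with entries in {0,1,2}."""

    values: np.ndarray
    snv_ids: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.snv_ids), len(self.subject_ids)):
            raise ValueError("genotype shape inconsistent with identifier lists")
        if len(set(self.snv_ids)) != len(self.snv_ids):
            raise ValueError("duplicate SNV identifiers")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject identifiers")

    def validate_entries(self) -> None:
        ok = np.isin(self.values, [0, 1, 2])
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"genotype entry outside {{0,1,2}} at SNV {self.snv_ids[i]}, "
                f"subject {self.subject_ids[j]}: {self.values[i, j]!r}"
            )

    def subset_snvs(self, keep_ids) -> "GenotypeMatrix":
        keep = set(keep_ids)
        idx = [i for i, s in enumerate(self.snv_ids) if s in keep]
        return GenotypeMatrix(
            self.values[idx], [self.snv_ids[i] for i in idx], list(self.subject_ids)
        )

    def subset_subjects(self, keep_ids) -> "GenotypeMatrix":
        keep = set(keep_ids)
        idx = [j for j, s in enumerate(self.subject_ids) if s in keep]
        return GenotypeMatrix(
            self.values[:, idx], list(self.snv_ids), [self.subject_ids[j] for j in idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.snv_ids, columns=self.subject_ids)


def impute_missing(
    geno: GenotypeMatrix, max_missingness: float = 0.05, missing_value=-1
) -> GenotypeMatrix:
    """Impute missing genotypes with the per-SNV mode; drop high-missingness SNVs.

    Missing entries are those equal to ``missing_value`` or NaN.  SNVs
    missing in more than ``max_missingness`` of subjects are dropped with
    a logged count.
    """
    vals = np.asarray(geno.values, dtype=float)
    miss = np.isnan(vals) | (vals == missing_value)
    frac = miss.mean(axis=1)
    keep = frac <= max_missingness
    if (~keep).any():
        log.info("dropping %d SNVs with missingness > %.0f%%", (~keep).sum(), 100 * max_missingness)
    vals, miss = vals[keep], miss[keep]
    out = vals.copy()
    for i in np.flatnonzero(miss.any(axis=1)):
        observed = vals[i, ~miss[i]].astype(int)
        counts = np.bincount(observed, minlength=3)
        out[i, miss[i]] = int(np.argmax(counts))
    gm = GenotypeMatrix(
        out.astype(int),
        [s for s, k in zip(geno.snv_ids, keep) if k],
        list(geno.subject_ids),
    )
    gm.validate_entries()
    return gm


def categorize_phenotype(
    values,
    control_cutoff: float,
    case_cutoff: float,
    orientation: str = "low_is_control",
) -> np.ndarray:
    """Label subjects control/case/excluded from trait cutoffs.

    With ``low_is_control`` (e.g. LDL cholesterol): control if value <
    control_cutoff, case if value >= case_cutoff, otherwise excluded.
    With ``high_is_control`` (e.g. HDL cholesterol): control if value >
    control_cutoff, case if value < case_cutoff.  A run with zero cases or
    zero controls cannot be factorized and is a hard error.
    """
    values = np.asarray(values, dtype=float)
    if orientation == "low_is_control":
        if control_cutoff > case_cutoff:
            raise ValueError("low_is_control requires control_cutoff <= case_cutoff")
        control = values < control_cutoff
        case = values >= case_cutoff
    elif orientation == "high_is_control":
        if control_cutoff < case_cutoff:
            raise ValueError("high_is_control requires control_cutoff >= case_cutoff")
        control = values > control_cutoff
        case = values < case_cutoff
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    labels = np.full(values.shape, "excluded", dtype=object)
    labels[control] = "control"
    labels[case] = "case"
    n_ctrl, n_case = int(control.sum()), int(case.sum())
    if n_ctrl == 0 or n_case == 0:
        raise ValueError(
            f"categorization produced {n_ctrl} controls and {n_case} cases; "
            "both classes are required"
        )
    return labels.astype(str)


def residualize_trait(values, covariates=None) -> np.ndarray:
    """Residuals of an OLS fit of the trait on covariates plus intercept.

    An empty covariate matrix reduces to mean-centering.  Rank-deficient
    designs raise an error naming the collinear columns.  The residuals
    are orthogonal to every covariate column and to the constant.
    """
    y = np.asarray(values, dtype=float)
    if covariates is None:
        X = np.empty((len(y), 0))
        names: list[str] = []
    elif isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values in trait or covariates; drop those rows first")
    # drop constant columns (absorbed by the intercept)
    keep = X.std(axis=0) > 0
    X, names = X[:, keep], [n for n, k in zip(names, keep) if k]
    design = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        corr = np.corrcoef(X, rowvar=False) if X.shape[1] > 1 else np.ones((1, 1))
        pairs = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 1 - 1e-8
        ]
        raise ValueError(f"rank-deficient covariate design; collinear columns: {pairs}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def select_snv_subset(
    seed_gene_ids,
    ppi_edges,
    annotations: pd.DataFrame,
) -> tuple[set[str], set[str]]:
    """SNV universe from seed genes and their first PPI neighbourhood.

    Returns (snv_ids, gene_ids) where the gene set is the seeds plus every
    gene directly interacting with a seed; seed genes absent from the PPI
    are retained as isolated nodes.  SNVs are all annotated variants whose
    gene is in that set.
    """
    seeds = set(seed_gene_ids)
    if not seeds:
        raise ValueError("empty seed gene set")
    genes = set(seeds)
    for a, b in ppi_edges:
        if a in seeds:
            genes.add(b)
        if b in seeds:
            genes.add(a)
    snvs = set(annotations.loc[annotations["gene"].isin(genes), "snv_id"])
    if not snvs:
        raise ValueError("no annotated SNVs fall in the selected gene set")
    return snvs, genes


def _logistic_pvalue(genotype: np.ndarray, y: np.ndarray) -> float:
    """Wald p-value of a single-SNV logistic regression (with fallback).

    Perfect separation or non-convergence falls back to the Cochran–
    Armitage-style score test on the additive coding.
    """
    import statsmodels.api as sm
    from scipy import stats

    X = sm.add_constant(genotype.astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        p = float(fit.pvalues[1])
        if np.isfinite(p):
            return p
    except Exception:
        pass
    # score-test fallback: correlation trend test
    g = genotype.astype(float)
    if g.std() == 0 or y.std() == 0:
        return 1.0
    r = np.corrcoef(g, y)[0, 1]
    z = r * np.sqrt(len(g))
    return float(2 * stats.norm.sf(abs(z)))


@dataclass
class ClumpResult:
    genotypes: GenotypeMatrix
    proxy_map: dict[str, str]  # removed SNV -> proxy SNV representing it
    annotations: pd.DataFrame


def clump_ld(
    geno: GenotypeMatrix,
    labels,
    annotations: pd.DataFrame,
    r2_threshold: float = 0.5,
) -> ClumpResult:
    """Collapse within-gene high-LD groups to their most associated proxy.

    Within each gene, SNV pairs whose genotype vectors have squared
    Pearson correlation above ``r2_threshold`` are grouped by transitive
    closure; the group member with the smallest single-SNV logistic
    p-value for case/control becomes the proxy (ties: smaller genomic
    position, then snv_id).  Non-proxies are removed; a proxy inherits the
    damaging annotations (deleterious / known-association flags, worst
    impact) of any removed group member so no functional information is
    lost.  Constant genotype rows are excluded from the r² computation
    (each stays its own group) with a warning.
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2_threshold must be in (0, 1]")
    labels = np.asarray(labels)
    classes = set(np.unique(labels))
    if not {"control", "case"} <= classes:
        raise ValueError("labels must contain both controls and cases")
    y = (labels == "case").astype(float)

    ann = annotations.set_index("snv_id")
    gene_of = ann["gene"].to_dict()
    pos_of = ann["position"].to_dict()

    vals = geno.values.astype(float)
    order = {s: i for i, s in enumerate(geno.snv_ids)}
    keep: list[str] = []
    proxy_map: dict[str, str] = {}
    inherited: dict[str, dict] = {}

    genes = pd.Series([gene_of[s] for s in geno.snv_ids], index=geno.snv_ids)
    for gene, members in genes.groupby(genes):
        snvs = list(members.index)
        idx = [order[s] for s in snvs]
        sub = vals[idx]
        sd = sub.std(axis=1)
        const = sd == 0
        if const.any():
            warnings.warn(
                f"{const.sum()} constant genotype row(s) in gene {gene} excluded from r2"
            )
        # adjacency over non-constant members
        nz = np.flatnonzero(~const)
        groups: list[list[int]] = [[k] for k in np.flatnonzero(const)]
        if nz.size:
            C = np.corrcoef(sub[nz])
            C = np.atleast_2d(C)
            r2 = C**2
            adj = r2 > r2_threshold
            # transitive closure via union-find over the adjacency
            parent = list(range(nz.size))

            def find(a: int) -> int:
                while parent[a] != a:
                    parent[a] = parent[parent[a]]
                    a = parent[a]
                return a

            for a in range(nz.size):
                for b in range(a + 1, nz.size):
                    if adj[a, b]:
                        ra, rb = find(a), find(b)
                        if ra != rb:
                            parent[rb] = ra
            comp: dict[int, list[int]] = {}
            for a in range(nz.size):
                comp.setdefault(find(a), []).append(int(nz[a]))
            groups.extend(comp.values())

        for grp in groups:
            gsnvs = [snvs[k] for k in grp]
            if len(gsnvs) == 1:
                keep.append(gsnvs[0])
                continue
            pvals = {s: _logistic_pvalue(vals[order[s]], y) for s in gsnvs}
            proxy = min(gsnvs, key=lambda s: (pvals[s], pos_of[s], s))
            keep.append(proxy)
            dropped = [s for s in gsnvs if s != proxy]
            for s in dropped:
                proxy_map[s] = proxy
            # functional impact of removed members is inherited by the proxy
            rows = ann.loc[gsnvs]
            info = inherited.setdefault(proxy, {})
            info["predicted_deleterious"] = bool(rows["predicted_deleterious"].any())
            info["known_association"] = bool(rows["known_association"].any())
            impact_rank = {"high": 0, "moderate": 1, "low": 2, "modifier": 3}
            worst = min(rows["impact_class"], key=lambda c: impact_rank[str(c).lower()])
            info["impact_class"] = worst

    keep_sorted = sorted(keep, key=lambda s: order[s])
    new_geno = geno.subset_snvs(keep_sorted)
    new_ann = annotations[annotations["snv_id"].isin(keep_sorted)].copy()
    for proxy, info in inherited.items():
        sel = new_ann["snv_id"] == proxy
        for col, val in info.items():
            new_ann.loc[sel, col] = val
    return ClumpResult(genotypes=new_geno, proxy_map=proxy_map, annotations=new_ann)
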