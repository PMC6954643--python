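"""Synthetic stratified genotype studies with known ground truth.

The generator emulates the situation the method is built for: a
case–control cohort drawn from several ancestral populations whose allele
frequencies have drifted apart (Balding–Nichols model), a phenotype driven
by a handful of causal variants clustered in functionally related genes,
and — optionally — a direct population→phenotype pathway that confounds
ancestry with the trait.  Everything downstream (annotations, PPI, seed
genes, LD duplicates) is generated alongside so the full pipeline can be
exercised end to end with the truth in hand.

Allele-frequency model: per SNV an ancestral frequency p₀ ~ U(maf range);
per population a drifted frequency p_k ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F),
where F is the differentiation (≈ Wright's F_ST); genotypes are
Binomial(2, p_k) per subject.  Phenotype model: per subject
logit P(case) = β₀ + effect·Σ_causal g + 2·confound·z_pop, with z_pop a
centered ±1 population code and β₀ tuned by bisection to hit the target
prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import networkx as nx

from .preprocess import GenotypeMatrix

# log-odds gap between two populations at confound_strength = 1
CONFOUND_SCALE = 2.0


@dataclass
class SimConfig:
    """Generating parameters of a synthetic study.

    Defaults are the standard fixture used throughout the test suite:
    600 subjects from two populations at F = 0.1, 800 SNVs in 40 genes,
    20 causal SNVs of per-allele log-odds 0.5 clustered in PPI-adjacent
    genes, and a population–phenotype confounding of 0.5.
    """

    m_subjects: int = 600
    n_snvs: int = 800
    n_genes: int = 40
    n_populations: int = 2
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    differentiation: float = 0.1
    n_causal: int = 20
    effect_size: float = 0.5
    causal_clustering: str = "network_neighbours"  # same_gene | network_neighbours | random
    confound_strength: float = 0.5
    damaging_fraction: float = 0.05
    prevalence: float = 0.4
    n_ld_duplicates: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_snvs:
            raise ValueError("n_causal cannot exceed n_snvs")
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("ancestral_maf_range must lie inside (0, 1)")
        if not 0 <= self.differentiation < 1:
            raise ValueError("differentiation must be in [0, 1)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        for name in ("m_subjects", "n_snvs", "n_genes", "n_populations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimBundle:
    """A generated study: genotypes, truth, and every pipeline input."""

    genotypes: GenotypeMatrix
    ancestry: np.ndarray  # population index per subject
    phenotypes: pd.DataFrame  # subject_id, trait, label, covariates
    causal_snvs: list[str]
    annotations: pd.DataFrame
    ppi_edges: list[tuple[str, str]]
    allele_freqs: pd.DataFrame  # snv_id, p0, p_pop0, p_pop1, ...
    config: SimConfig

    @property
    def labels(self) -> np.ndarray:
        return self.phenotypes["label"].to_numpy()

    @property
    def known_genes(self) -> list[str]:
        known = self.annotations.loc[self.annotations["known_association"], "gene"]
        return sorted(set(known))

    @property
    def causal_genes(self) -> list[str]:
        ann = self.annotations.set_index("snv_id")
        return sorted({ann.loc[s, "gene"] for s in self.causal_snvs})


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, np.ndarray, pd.DataFrame]:
    """Balding–Nichols genotypes for a stratified cohort.

    Returns the genotype matrix, per-subject population labels (balanced
    across populations) and the ancestral/per-population allele-frequency
    table.  F = 0 short-circuits the Beta draw so every population shares
    the ancestral frequency exactly.
    """
    rng = rng or np.random.default_rng(config.seed)
    n, m, K = config.n_snvs, config.m_subjects, config.n_populations
    F = config.differentiation
    lo, hi = config.ancestral_maf_range
    p0 = rng.uniform(lo, hi, size=n)
    if F == 0:
        pk = np.tile(p0[:, None], (1, K))
    else:
        a = p0 * (1 - F) / F
        b = (1 - p0) * (1 - F) / F
        pk = rng.beta(a[:, None], b[:, None], size=(n, K))
    ancestry = np.arange(m) % K  # balanced assignment
    geno = rng.binomial(2, pk[:, ancestry])
    snv_ids = [f"rs{i + 1:05d}" for i in range(n)]
    subject_ids = [f"S{j + 1:04d}" for j in range(m)]
    freqs = pd.DataFrame({"snv_id": snv_ids, "p0": p0})
    for k in range(K):
        freqs[f"p_pop{k}"] = pk[:, k]
    return GenotypeMatrix(geno, snv_ids, subject_ids), ancestry, freqs


def plant_phenotypes(
    genotypes: GenotypeMatrix,
    ancestry: np.ndarray,
    causal_set,
    effect_size: float,
    confound_strength: float,
    seed: int,
    prevalence: float = 0.4,
) -> pd.DataFrame:
    """Draw case/control labels from a logistic model on causal burden.

    logit P(case) = β₀ + effect_size·burden + 2·confound_strength·z_pop,
    where burden is the summed allele count over causal SNVs and z_pop the
    centered population code.  β₀ is found by bisection so the expected
    prevalence is within 0.02 of the target.  Also emits a continuous
    liability trait and two pure-noise covariates (age, bmi).
    """
    rng = np.random.default_rng(seed)
    causal_set = list(causal_set)
    idx = {s: i for i, s in enumerate(genotypes.snv_ids)}
    missing = [s for s in causal_set if s not in idx]
    if missing:
        raise ValueError(f"causal SNVs not in genotype matrix: {missing[:5]}")
    burden = (
        genotypes.values[[idx[s] for s in causal_set]].sum(axis=0)
        if causal_set
        else np.zeros(len(genotypes.subject_ids))
    )
    pops = np.asarray(ancestry, dtype=float)
    z = pops - pops.mean()
    if z.std() > 0:
        z = z / z.std()
    eta_base = effect_size * burden + CONFOUND_SCALE * confound_strength * z

    def mean_prev(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta_base)))))

    lo, hi = -30.0, 30.0
    if not mean_prev(lo) <= prevalence <= mean_prev(hi):
        raise ValueError(f"target prevalence {prevalence} unattainable")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if mean_prev(mid) < prevalence:
            lo = mid
        else:
            hi = mid
    b0 = 0.5 * (lo + hi)
    if abs(mean_prev(b0) - prevalence) > 0.02:
        raise ValueError("bisection failed to reach target prevalence within 0.02")

    eta = b0 + eta_base
    prob = 1.0 / (1.0 + np.exp(-eta))
    case = rng.random(len(prob)) < prob
    m = len(prob)
    return pd.DataFrame(
        {
            "subject_id": genotypes.subject_ids,
            "trait": eta + rng.logistic(0, 1, size=m),  # latent liability scale
            "label": np.where(case, "case", "control"),
            "age": rng.normal(50, 10, size=m).round(1),
            "bmi": rng.normal(27, 4, size=m).round(1),
        }
    )


def _pick_causal_genes(
    G: nx.Graph, gene_ids: list[str], sizes: dict[str, int], n_causal: int, mode: str,
    rng: np.random.Generator,
) -> list[str]:
    if mode == "same_gene":
        big = max(gene_ids, key=lambda g: sizes[g])
        if sizes[big] < n_causal:
            raise ValueError("no single gene can harbour all causal SNVs")
        return [big]
    if mode == "network_neighbours":
        target = max(2, round(n_causal / 4))
        start = max(G.degree, key=lambda kv: kv[1])[0]
        order = [start] + [v for _, v in nx.bfs_edges(G, start)]
        chosen: list[str] = []
        cap = 0
        for g in order:
            chosen.append(g)
            cap += sizes[g]
            if len(chosen) >= target and cap >= n_causal:
                break
        if cap < n_causal:
            raise ValueError("PPI neighbourhood too small for requested causal count")
        return chosen
    if mode == "random":
        return list(gene_ids)
    raise ValueError(f"unknown causal_clustering mode {mode!r}")


def simulate_annotations_and_ppi(
    config: SimConfig,
    snv_ids: list[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[tuple[str, str]], list[str]]:
    """Gene blocks, damaging flags, a scale-free PPI, and causal placement.

    SNVs are partitioned into contiguous gene blocks; the PPI on genes is
    a preferential-attachment (Barabási–Albert) graph.  Causal SNVs are
    placed according to ``config.causal_clustering``; a greedy dominating
    subset of the causal genes is flagged as known-association seed genes
    (one causal SNV in each carries the known flag), so every causal gene
    is a seed or a first PPI neighbour of one.
    """
    n, G_n = config.n_snvs, config.n_genes
    gene_ids = [f"G{g + 1:03d}" for g in range(G_n)]
    blocks = np.array_split(np.arange(n), G_n)
    gene_of = np.empty(n, dtype=object)
    position = np.empty(n, dtype=int)
    for g, blk in enumerate(blocks):
        gene_of[blk] = gene_ids[g]
        position[blk] = (g + 1) * 1_000_000 + 100 * (np.arange(len(blk)) + 1)
    sizes = {gene_ids[g]: len(blk) for g, blk in enumerate(blocks)}

    ppi_graph = nx.barabasi_albert_graph(G_n, 2, seed=int(rng.integers(2**31 - 1)))
    mapping = {i: gene_ids[i] for i in range(G_n)}
    ppi_graph = nx.relabel_nodes(ppi_graph, mapping)
    ppi_edges = [tuple(sorted(e)) for e in ppi_graph.edges()]

    # causal placement
    causal_genes = _pick_causal_genes(
        ppi_graph, gene_ids, sizes, config.n_causal, config.causal_clustering, rng
    )
    snv_by_gene = {g: np.flatnonzero(gene_of == g) for g in gene_ids}
    causal_idx: list[int] = []
    if config.causal_clustering == "random":
        causal_idx = list(rng.choice(n, size=config.n_causal, replace=False))
    else:
        pools = [list(snv_by_gene[g]) for g in causal_genes]
        for p in pools:
            rng.shuffle(p)
        gi = 0
        while len(causal_idx) < config.n_causal:
            pool = pools[gi % len(pools)]
            if pool:
                causal_idx.append(pool.pop())
            gi += 1
    causal_snvs = [snv_ids[i] for i in sorted(causal_idx)]
    causal_gene_set = sorted({gene_of[i] for i in causal_idx})

    # damaging flags at the background rate
    impact = np.where(rng.random(n) < 0.5, "low", "modifier").astype(object)
    deleterious = np.zeros(n, dtype=bool)
    dmg = rng.random(n) < config.damaging_fraction
    mech = rng.random(n)
    impact[dmg & (mech < 0.4)] = "high"
    impact[dmg & (mech >= 0.4) & (mech < 0.8)] = "moderate"
    deleterious[dmg & (mech >= 0.8)] = True

    # seed genes (known loci).  In network_neighbours mode the seeds are
    # non-causal PPI neighbours of the causal genes — the replication
    # scenario the method targets: known loci sit next to the novel causal
    # genes, every causal gene is in the first neighbourhood of a seed,
    # and association signal can only reach a seed through the network.
    # One causal SNV per causal gene is additionally flagged deleterious
    # so a damaging-damaging edge into the seed exists.  Other clustering
    # modes flag half of the causal genes themselves as known.
    known = np.zeros(n, dtype=bool)
    adj = {g: set(ppi_graph.neighbors(g)) for g in gene_ids}
    seed_genes: list[str] = []
    if config.causal_clustering == "network_neighbours":
        for g in causal_gene_set:
            if any(h in adj[g] for h in seed_genes):
                continue
            options = sorted(adj[g] - set(causal_gene_set))
            if options:
                pick = max(options, key=lambda h: ppi_graph.degree[h])
                seed_genes.append(pick)
            else:
                seed_genes.append(g)  # isolated pocket: the gene seeds itself
        for g in seed_genes:
            known[int(snv_by_gene[g][0])] = True
        for g in causal_gene_set:
            in_gene = [i for i in causal_idx if gene_of[i] == g]
            if in_gene:
                deleterious[in_gene[0]] = True
    else:
        for g in causal_gene_set:
            if g in seed_genes or any(h in adj[g] for h in seed_genes):
                continue
            seed_genes.append(g)
        target_seeds = max(2, int(np.ceil(len(causal_gene_set) / 2)))
        for g in causal_gene_set:
            if len(seed_genes) >= target_seeds:
                break
            if g not in seed_genes:
                seed_genes.append(g)
        for g in seed_genes:
            in_gene = [i for i in causal_idx if gene_of[i] == g]
            flag = in_gene[0] if in_gene else int(snv_by_gene[g][0])
            known[flag] = True

    ann = pd.DataFrame(
        {
            "snv_id": snv_ids,
            "gene": gene_of,
            "position": position,
            "impact_class": impact,
            "predicted_deleterious": deleterious,
            "known_association": known,
        }
    )
    return ann, ppi_edges, causal_snvs


def _add_ld_duplicates(
    geno: GenotypeMatrix, ann: pd.DataFrame, n_dup: int, rng: np.random.Generator
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Append exact-copy twins of ``n_dup`` SNVs right after their originals."""
    if n_dup == 0:
        return geno, ann
    n = len(geno.snv_ids)
    picks = sorted(rng.choice(n, size=min(n_dup, n), replace=False))
    rows, ids = [], []
    ann_rows = []
    ann_ix = ann.set_index("snv_id")
    for i in range(n):
        rows.append(geno.values[i])
        ids.append(geno.snv_ids[i])
        if i in picks:
            twin = f"{geno.snv_ids[i]}_dup"
            rows.append(geno.values[i].copy())
            ids.append(twin)
            rec = ann_ix.loc[geno.snv_ids[i]].copy()
            rec["position"] = int(rec["position"]) + 1
            # the twin itself carries no functional annotation
            rec["impact_class"] = "modifier"
            rec["predicted_deleterious"] = False
            rec["known_association"] = False
            ann_rows.append((twin, rec))
    new_geno = GenotypeMatrix(np.asarray(rows), ids, list(geno.subject_ids))
    add = pd.DataFrame(
        {"snv_id": [t for t, _ in ann_rows]}
        | {c: [r[c] for _, r in ann_rows] for c in ann.columns if c != "snv_id"}
    )
    new_ann = pd.concat([ann, add], ignore_index=True)
    order = {s: k for k, s in enumerate(ids)}
    new_ann = new_ann.sort_values("snv_id", key=lambda s: s.map(order)).reset_index(drop=True)
    return new_geno, new_ann


def simulate_bundle(config: SimConfig | None = None, **overrides) -> SimBundle:
    """Generate a complete synthetic study from a single seed."""
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = SimConfig(**{**asdict(config), **overrides})
    ss = np.random.SeedSequence(config.seed)
    r_geno, r_ann, r_phen = (np.random.default_rng(s) for s in ss.spawn(3))

    geno, ancestry, freqs = simulate_genotypes(config, r_geno)
    ann, ppi, causal = simulate_annotations_and_ppi(config, geno.snv_ids, r_ann)
    geno, ann = _add_ld_duplicates(geno, ann, config.n_ld_duplicates, r_ann)
    phen = plant_phenotypes(
        geno,
        ancestry,
        causal,
        config.effect_size,
        config.confound_strength,
        seed=int(r_phen.integers(2**31 - 1)),
        prevalence=config.prevalence,
    )
    return SimBundle(
        genotypes=geno,
        ancestry=ancestry,
        phenotypes=phen,
        causal_snvs=causal,
        annotations=ann,
        ppi_edges=ppi,
        allele_freqs=freqs,
        config=config,
    )


def simulate_block_genotypes(
    n_snvs: int = 300,
    m_subjects: int = 200,
    n_blocks: int = 3,
    seed: int = 0,
    profiles: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genotypes with planted SNV blocks for rank-selection tests.

    Subjects split into ``n_blocks`` groups and each SNV block is common
    in exactly one subject group (allele frequency 0.85 there, 0.1
    elsewhere), so the SNV profiles form ``n_blocks`` well-separated
    directions.  Returns (R, snv block labels, subject group labels).
    """
    rng = np.random.default_rng(seed)
    if profiles is None:
        profiles = np.full((n_blocks, n_blocks), 0.1) + np.eye(n_blocks) * 0.75
    profiles = np.asarray(profiles)
    if len(profiles) < n_blocks:
        raise ValueError("not enough frequency profiles for requested blocks")
    snv_block = np.arange(n_snvs) % n_blocks
    groups = np.arange(m_subjects) % profiles.shape[1]
    p = profiles[snv_block][:, groups]  # n × m frequencies
    R = rng.binomial(2, p)
    return R, snv_block, groups
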