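"""Readers and writers for the plain-text input/output formats.

Genotypes: TSV with an ``snv_id`` first column and one column per subject
(entries 0/1/2, or -1/NA for missing), or a VCF of biallelic sites from
which the additive dosage is derived from GT.  Phenotypes: TSV keyed by
``subject_id``.  Annotations: TSV with columns snv_id, gene, position,
impact_class, deleterious, known_association.  PPI: two-column TSV of
gene identifiers.  SNV networks round-trip as edge + node-class TSVs; the
Laplacian is never serialized (it is recomputed).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .network import SnvNetwork
from .preprocess import GenotypeMatrix


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz"):
        return read_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    snv_col = df.columns[0]
    snv_ids = df[snv_col].astype(str).tolist()
    values = df.drop(columns=[snv_col]).to_numpy()
    return GenotypeMatrix(values, snv_ids, [str(c) for c in df.columns[1:]])


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    df = geno.to_frame()
    df.index.name = "snv_id"
    df.to_csv(path, sep="\t")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Additive dosages from a VCF of biallelic sites (requires cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    subject_ids = list(vcf.samples)
    snv_ids: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic site {var.ID or var.POS}; decompose first")
        snv_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        g = np.asarray(var.gt_types, dtype=int)  # 0/1/2, 3 = unknown
        g[g == 3] = -1
        rows.append(g)
    return GenotypeMatrix(np.asarray(rows), snv_ids, subject_ids)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValueError("phenotype table needs a subject_id column")
    return df


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snv_id": str, "gene": str})
    rename = {"deleterious": "predicted_deleterious"}
    df = df.rename(columns=rename)
    required = {
        "snv_id", "gene", "position", "impact_class",
        "predicted_deleterious", "known_association",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    for col in ("predicted_deleterious", "known_association"):
        df[col] = df[col].map(
            lambda v: str(v).strip().lower() in {"true", "1", "yes", "t"}
        )
    return df


def read_ppi(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("PPI table needs two gene columns")
    # tolerate a header row of non-data labels
    if set(df.iloc[0].str.lower()) & {"gene_a", "gene_b", "gene1", "gene2"}:
        df = df.iloc[1:]
    return [tuple(sorted((a, b))) for a, b in zip(df[0], df[1])]


def write_ppi(edges, path: str | Path) -> None:
    pd.DataFrame(edges).to_csv(path, sep="\t", header=False, index=False)


def write_network(net: SnvNetwork, edge_path: str | Path, node_path: str | Path) -> None:
    net.to_edge_frame().to_csv(edge_path, sep="\t", index=False)
    pd.DataFrame(
        {"snv_id": net.snv_ids, "class": net.classes, "gene": net.genes}
    ).to_csv(node_path, sep="\t", index=False)


def read_network(edge_path: str | Path, node_path: str | Path) -> SnvNetwork:
    nodes = pd.read_csv(node_path, sep="\t", dtype=str)
    edges = pd.read_csv(edge_path, sep="\t")
    ids = nodes["snv_id"].tolist()
    pos = {s: i for i, s in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)))
    for a, b, w in zip(edges["snv_a"], edges["snv_b"], edges["weight"]):
        W[pos[str(a)], pos[str(b)]] = W[pos[str(b)], pos[str(a)]] = float(w)
    return SnvNetwork(
        snv_ids=ids,
        classes=nodes["class"].to_numpy(),
        genes=nodes["gene"].to_numpy(),
        W=W,
    )


def write_bundle(bundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic study in the exact formats the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "annotations": out / "annotations.tsv",
        "ppi": out / "ppi.tsv",
        "truth": out / "truth.json",
    }
    write_genotypes(bundle.genotypes, paths["genotypes"])
    phen = bundle.phenotypes.copy()
    phen["population"] = bundle.ancestry
    phen.to_csv(paths["phenotypes"], sep="\t", index=False)
    bundle.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    write_ppi(bundle.ppi_edges, paths["ppi"])
    import json
    from dataclasses import asdict

    truth = {
        "causal_snvs": list(bundle.causal_snvs),
        "known_genes": bundle.known_genes,
        "config": asdict(bundle.config),
    }
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths


def read_bundle(in_dir: str | Path):
    """Round-trip companion of :func:`write_bundle`."""
    import json

    from .simdata import SimBundle, SimConfig

    d = Path(in_dir)
    geno = read_genotypes(d / "genotypes.tsv")
    phen = read_phenotypes(d / "phenotypes.tsv")
    ann = read_annotations(d / "annotations.tsv")
    ppi = read_ppi(d / "ppi.tsv")
    truth = json.loads((d / "truth.json").read_text())
    cfg = truth["config"]
    cfg["ancestral_maf_range"] = tuple(cfg["ancestral_maf_range"])
    return SimBundle(
        genotypes=geno,
        ancestry=phen["population"].to_numpy(),
        phenotypes=phen.drop(columns=["population"]),
        causal_snvs=truth["causal_snvs"],
        annotations=ann,
        ppi_edges=ppi,
        allele_freqs=pd.DataFrame(),
        config=SimConfig(**cfg),
    )
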