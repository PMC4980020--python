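"""Pleiotropy detection, gene assignment, network edges, catalog matching.

These operations consume the pooled (meta) result table: SNPs associated
with two or more distinct ICD-9 categories are flagged as potentially
pleiotropic; SNPs are assigned to genes whose (flank-extended) interval
contains them; phenotype-gene and gene-pathway edges are emitted as a plain
edge-list table; and replicated SNPs are annotated against a user-supplied
GWAS-catalog extract at a reported-p threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParseError

logger = logging.getLogger(__name__)


@dataclass
class GeneRegion:
    """Gene interval, stored 1-based inclusive."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")


def detect_pleiotropy(meta_results: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP distinct phenotype categories among replicated results.

    Returns one row per SNP with its category set, the count, and a flag for
    >= 2 distinct categories (cross-phenotype association).  The frame's
    ``attrs['pleiotropy_ratio']`` holds flagged/total.
    """
    if meta_results.empty:
        out = pd.DataFrame(columns=["snp_id", "categories", "n_categories", "pleiotropic"])
        out.attrs["pleiotropy_ratio"] = float("nan")
        return out
    grouped = (
        meta_results.groupby("snp_id")["category"]
        .agg(lambda s: sorted(set(s)))
        .reset_index()
        .rename(columns={"category": "categories"})
    )
    grouped["n_categories"] = grouped["categories"].map(len)
    grouped["pleiotropic"] = grouped["n_categories"] >= 2
    grouped.attrs["pleiotropy_ratio"] = float(grouped["pleiotropic"].mean())
    return grouped


def assign_genes(
    snps: pd.DataFrame,
    regions: list[GeneRegion],
    flank: int = 50_000,
    nearest: bool = False,
) -> pd.DataFrame:
    """Map SNPs to genes within ``flank`` bases (default 50 kb).

    ``snps`` needs columns ``snp_id, chrom, pos`` (1-based).  A SNP is
    assigned to every gene whose interval, extended by ``flank`` on both
    sides, contains its position; SNPs hitting nothing get gene "unmapped"
    (or, with ``nearest=True``, the nearest gene on the same chromosome).
    Chromosome mismatches are non-overlaps, never errors.
    """
    rows = []
    for _, s in snps.iterrows():
        pos, chrom = int(s["pos"]), str(s["chrom"])
        hits = [
            r.gene
            for r in regions
            if str(r.chrom) == chrom and (r.start - flank) <= pos <= (r.end + flank)
        ]
        if not hits and nearest:
            same = [r for r in regions if str(r.chrom) == chrom]
            if same:
                nearest_gene = min(
                    same, key=lambda r: max(r.start - pos, pos - r.end, 0)
                )
                hits = [nearest_gene.gene]
        if not hits:
            hits = ["unmapped"]
        for g in sorted(set(hits)):
            rows.append((s["snp_id"], g))
    return pd.DataFrame(rows, columns=["snp_id", "gene"])


def build_network(
    meta_results: pd.DataFrame,
    gene_map: pd.DataFrame,
    pathway_sets: dict[str, set] | None = None,
) -> pd.DataFrame:
    """Edge list linking phenotype categories, genes and pathways.

    Phenotype-gene edges are weighted by the number of distinct SNPs in that
    gene supporting the category; gene-pathway edges come from set
    membership (weight = number of distinct supporting SNPs for the gene).
    Genes absent from every pathway are logged once and get no pathway edge.
    """
    cols = ["node_a", "node_b", "edge_type", "weight"]
    if meta_results.empty:
        return pd.DataFrame(columns=cols)
    merged = meta_results.merge(gene_map, on="snp_id", how="inner")
    merged = merged[merged["gene"] != "unmapped"]
    if merged.empty:
        return pd.DataFrame(columns=cols)

    pg = (
        merged.groupby(["category", "gene"])["snp_id"]
        .nunique()
        .reset_index(name="weight")
    )
    edges = [
        (r["category"], r["gene"], "phenotype-gene", int(r["weight"]))
        for _, r in pg.iterrows()
    ]
    if pathway_sets:
        gene_support = merged.groupby("gene")["snp_id"].nunique()
        for gene, support in gene_support.items():
            pathways = [name for name, members in pathway_sets.items() if gene in members]
            if not pathways:
                logger.info("gene %s not in any supplied pathway set", gene)
                continue
            for pw in pathways:
                edges.append((gene, pw, "gene-pathway", int(support)))
    return pd.DataFrame(edges, columns=cols)


def to_networkx(edges: pd.DataFrame):
    """Edge list -> networkx.Graph with typed nodes and weighted edges."""
    import networkx as nx

    g = nx.Graph()
    for _, e in edges.iterrows():
        type_a, type_b = e["edge_type"].split("-")
        g.add_node(e["node_a"], node_type=type_a)
        g.add_node(e["node_b"], node_type=type_b)
        g.add_edge(e["node_a"], e["node_b"], weight=e["weight"], edge_type=e["edge_type"])
    return g


def match_catalog(
    meta_results: pd.DataFrame,
    catalog: pd.DataFrame,
    trait_map: pd.DataFrame | None = None,
    p_max: float = 1e-5,
) -> pd.DataFrame:
    """Annotate replicated SNPs against a GWAS-catalog extract.

    ``catalog`` needs columns ``snp_id, trait, p, source``; rows with
    reported p >= ``p_max`` (strict inequality at the threshold) are
    ignored.  A result is "previously reported" when its SNP matches a
    catalog row whose trait maps to the result's phenotype category via the
    user-supplied ``trait_map`` (columns ``category, trait``); otherwise it
    is "novel for this phenotype" (with any same-SNP catalog traits listed).
    """
    bad = catalog[(catalog["p"] <= 0) | (catalog["p"] > 1) | catalog["p"].isna()]
    if len(bad):
        logger.warning("skipping %d malformed catalog rows", len(bad))
    cat = catalog.drop(bad.index)
    cat = cat[cat["p"] < p_max]

    snp_traits = cat.groupby("snp_id")["trait"].agg(lambda s: sorted(set(s)))
    mapped = None
    if trait_map is not None and len(trait_map):
        mapped = trait_map.groupby("category")["trait"].agg(set).to_dict()

    rows = []
    seen = meta_results[["snp_id", "category"]].drop_duplicates()
    for _, r in seen.iterrows():
        traits = snp_traits.get(r["snp_id"], [])
        reported = False
        if traits and mapped is not None:
            wanted = mapped.get(r["category"], set())
            reported = bool(wanted.intersection(traits))
        rows.append(
            (
                r["snp_id"], r["category"], ";".join(traits),
                "previously reported" if reported else "novel for this phenotype",
            )
        )
    return pd.DataFrame(rows, columns=["snp_id", "category", "catalog_traits", "status"])


def read_gmt(path) -> dict[str, set]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: GMT line needs name, description, genes")
            sets[parts[0]] = set(filter(None, parts[2:]))
    return sets


def read_gene_regions(path) -> list[GeneRegion]:
    """Gene regions from BED (0-based half-open, name in column 4) or a
    4-column TSV ``gene, chrom, start, end`` (1-based inclusive)."""
    regions = []
    is_bed = str(path).endswith(".bed")
    if is_bed:
        from .genoqc import read_bed

        for _, r in read_bed(path).iterrows():
            regions.append(GeneRegion(gene=r["name"], chrom=r["chrom"], start=r["start"] + 1, end=r["end"]))
    else:
        df = pd.read_csv(path, sep="\t")
        need = {"gene", "chrom", "start", "end"}
        if not need.issubset(df.columns):
            raise ParseError(f"{path}: gene TSV needs columns {sorted(need)}")
        for _, r in df.iterrows():
            regions.append(GeneRegion(gene=str(r["gene"]), chrom=str(r["chrom"]), start=int(r["start"]), end=int(r["end"])))
    return regions
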