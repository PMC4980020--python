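"""End-to-end two-site pipeline driver.

Stages: derive case/control statuses from billing events -> genotype QC
(info score, call rates, MAF), relatedness removal, LD prune (the pruned
count is the Bonferroni denominator), principal components -> per-site
covariate-adjusted logistic scan -> cross-site replication at exact-code and
category level -> sample-size-weighted signed-Z pooled analysis ->
pleiotropy/network/catalog outputs.  A JSON manifest records input
checksums, thresholds and per-stage row counts; identical inputs and config
reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .assoc import bonferroni_threshold, run_phewas
from .downstream import (build_network, detect_pleiotropy, match_catalog,
                         read_gene_regions, read_gmt)
from .genoqc import (apply_qc_filters, compute_pcs, estimate_relatedness,
                     ld_prune, read_bed, remove_related, select_snps_by_regions)
from .meta import meta_analyze
from .phenotypes import derive_phenotypes
from .replicate import match_category, match_exact

logger = logging.getLogger(__name__)

# Method-of-moments pi-hat needs thousands of markers to separate relatives
# from noise: below the minimum the removal stage is skipped (and logged),
# above the maximum a uniform SNP subsample keeps the O(n^2 L) cost bounded.
RELATEDNESS_MIN_SNPS = 2000
RELATEDNESS_MAX_SNPS = 2000


@dataclass
class SiteInputs:
    site: str
    genotypes: str
    events: str
    covariates: str
    info_sidecar: str | None = None


@dataclass
class Thresholds:
    case_min_instances: int = 4
    min_cases: int = 11
    min_info: float = 0.9
    snp_call: float = 0.99
    sample_call: float = 0.99
    min_maf: float = 0.01
    pi_hat: float = 0.1875
    r2: float = 0.3
    ld_window: int = 50
    ld_step: int = 5
    n_pcs: int = 5
    p_replication: float = 0.01
    alpha: float = 0.05
    flank: int = 50_000
    catalog_p: float = 1e-5

    def __post_init__(self):
        if not (0 < self.p_replication <= 1 and 0 < self.alpha <= 1 and 0 < self.catalog_p <= 1):
            raise ValueError("p-value thresholds must lie in (0, 1]")
        if self.case_min_instances < 1 or self.min_cases < 1:
            raise ValueError("instance/case thresholds must be positive")
        if not (0 <= self.r2 <= 1):
            raise ValueError("r2 must lie in [0, 1]")


@dataclass
class PipelineConfig:
    site_a: SiteInputs
    site_b: SiteInputs
    out_dir: str
    thresholds: Thresholds = field(default_factory=Thresholds)
    gene_regions: str | None = None
    pathways: str | None = None
    catalog: str | None = None
    trait_map: str | None = None
    regions_bed: str | None = None
    snp_list: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sites = raw["sites"]
        thr = Thresholds(**raw.get("thresholds", {}))
        ann = raw.get("annotation", {})
        return cls(
            site_a=SiteInputs(site="site_a", **sites["a"]),
            site_b=SiteInputs(site="site_b", **sites["b"]),
            out_dir=raw["out_dir"],
            thresholds=thr,
            gene_regions=ann.get("gene_regions"),
            pathways=ann.get("pathways"),
            catalog=ann.get("catalog"),
            trait_map=ann.get("trait_map"),
            regions_bed=raw.get("regions_bed"),
            snp_list=raw.get("snp_list"),
            seed=raw.get("seed", 0),
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_genotypes(inputs: SiteInputs):
    if str(inputs.genotypes).endswith((".vcf", ".vcf.gz")):
        return io.read_vcf(inputs.genotypes, info_sidecar=inputs.info_sidecar)
    return io.read_dosage_tsv(inputs.genotypes)


def run_site(inputs: SiteInputs, thr: Thresholds, out: Path, regions=None, snp_list=None):
    """One site: derive -> QC -> prune/PCs -> scan.  Returns per-stage state."""
    site = inputs.site
    geno = _load_genotypes(inputs)
    events = io.read_events_csv(inputs.events)
    covars = io.read_covariates_tsv(inputs.covariates)
    counts = {"snps_in": geno.n_snps, "samples_in": geno.n_samples,
              "event_rows": len(events)}

    if regions is not None or snp_list:
        geno = select_snps_by_regions(geno, regions=regions, snp_list=snp_list)
        counts["snps_after_region_filter"] = geno.n_snps

    statuses = derive_phenotypes(
        events, list(covars["person_id"]),
        case_min_instances=thr.case_min_instances, min_cases=thr.min_cases,
    )
    io.write_status_matrix(statuses.statuses, out / f"{site}.status.tsv")
    io.write_table(statuses.summary, out / f"{site}.phenotype_summary.tsv")
    counts["codes_seen"] = len(statuses.summary)
    counts["codes_retained"] = int(statuses.summary["retained"].sum())

    geno, report = apply_qc_filters(
        geno, min_info=thr.min_info, snp_call=thr.snp_call,
        sample_call=thr.sample_call, min_maf=thr.min_maf,
    )
    io.write_table(report.to_frame(), out / f"{site}.qc_report.tsv")
    counts["snps_post_qc"] = geno.n_snps

    if geno.n_snps >= RELATEDNESS_MIN_SNPS:
        ibd_geno = geno
        if geno.n_snps > RELATEDNESS_MAX_SNPS:
            stride = int(np.ceil(geno.n_snps / RELATEDNESS_MAX_SNPS))
            mask = np.zeros(geno.n_snps, dtype=bool)
            mask[::stride] = True
            ibd_geno = geno.subset(snp_mask=mask)
        pairs = estimate_relatedness(ibd_geno, min_pi_hat=thr.pi_hat / 2)
        keep = remove_related(pairs, geno, threshold=thr.pi_hat)
        counts["relatedness_removal"] = "run"
    else:
        logger.warning(
            "[%s] only %d post-QC SNPs (<%d): pi-hat too noisy, relatedness "
            "removal skipped", site, geno.n_snps, RELATEDNESS_MIN_SNPS,
        )
        keep = sorted(geno.samples)
        counts["relatedness_removal"] = "skipped_too_few_snps"
    io.write_keep_list(keep, out / f"{site}.samples.keep")
    counts["samples_post_relatedness"] = len(keep)
    keep_set = set(keep)
    geno = geno.subset(sample_mask=[s in keep_set for s in geno.samples])
    statuses.statuses = statuses.statuses.loc[
        [p for p in statuses.statuses.index if p in keep_set]
    ]

    pruned = ld_prune(geno, r2_max=thr.r2, window=thr.ld_window, step=thr.ld_step)
    io.write_keep_list(pruned, out / f"{site}.snps.pruned")
    counts["snps_ld_pruned"] = len(pruned)

    pruned_geno = geno.subset(snp_mask=geno.snps["snp_id"].isin(set(pruned)).to_numpy())
    pcs = compute_pcs(pruned_geno, k=thr.n_pcs)
    covars = covars.merge(pcs.to_frame(), on="person_id", how="inner")
    io.write_covariates_tsv(covars, out / f"{site}.covariates_pcs.tsv")

    results = run_phewas(geno, statuses, covars, site=site, p_ceiling=thr.p_replication)
    io.write_table(results.table, out / f"{site}.assoc.tsv")
    counts["fits"] = results.n_fits
    counts["fits_skipped"] = results.n_skipped
    counts["fits_nonconverged"] = results.n_nonconverged
    counts["assoc_rows_below_ceiling"] = len(results.table)
    counts["bonferroni_threshold"] = bonferroni_threshold(
        max(len(pruned), 1), max(results.n_phenotypes, 1), thr.alpha
    )
    logger.info("[%s] %s", site, counts)
    return geno, results, counts


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full two-site pipeline; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds

    regions = read_bed(config.regions_bed) if config.regions_bed else None
    snp_list = io.read_keep_list(config.snp_list) if config.snp_list else None

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": asdict(thr),
        "inputs": {},
        "stages": {},
    }
    for si in (config.site_a, config.site_b):
        for kind in ("genotypes", "events", "covariates"):
            manifest["inputs"][f"{si.site}.{kind}"] = _sha256(getattr(si, kind))

    results = {}
    for si in (config.site_a, config.site_b):
        _, res, counts = run_site(si, thr, out, regions=regions, snp_list=snp_list)
        results[si.site] = res
        manifest["stages"][si.site] = counts

    res_a, res_b = results["site_a"].table, results["site_b"].table
    pairs_exact = match_exact(res_a, res_b, p_threshold=thr.p_replication)
    pairs_cat = match_category(res_a, res_b, p_threshold=thr.p_replication)
    io.write_table(pairs_exact, out / "replicated.exact.tsv")
    io.write_table(pairs_cat, out / "replicated.category.tsv")
    manifest["stages"]["replication"] = {
        "exact_pairs": len(pairs_exact), "category_pairs": len(pairs_cat),
    }

    meta_exact = meta_analyze(pairs_exact)
    meta_cat = meta_analyze(pairs_cat)
    io.write_table(meta_exact, out / "meta.exact.tsv")
    io.write_table(meta_cat, out / "meta.category.tsv")
    manifest["stages"]["meta"] = {
        "exact_rows": len(meta_exact), "category_rows": len(meta_cat),
    }

    pleio = detect_pleiotropy(meta_cat)
    io.write_table(pleio, out / "pleiotropy.tsv")
    manifest["stages"]["pleiotropy"] = {
        "snps": len(pleio),
        "flagged": int(pleio["pleiotropic"].sum()) if len(pleio) else 0,
    }

    if config.gene_regions:
        gene_regions = read_gene_regions(config.gene_regions)
        snp_pos = pd.concat(
            [results["site_a"].table, results["site_b"].table]
        )[["snp_id"]].drop_duplicates()
        # positions come from site A's panel metadata written alongside results
        geno_a = _load_genotypes(config.site_a)
        snp_pos = snp_pos.merge(geno_a.snps[["snp_id", "chrom", "pos"]], on="snp_id")
        from .downstream import assign_genes

        meta_snps = snp_pos[snp_pos["snp_id"].isin(set(meta_cat["snp_id"]))]
        gene_map = assign_genes(meta_snps, gene_regions, flank=thr.flank)
        io.write_table(gene_map, out / "gene_assignments.tsv")
        pathway_sets = read_gmt(config.pathways) if config.pathways else None
        edges = build_network(meta_cat, gene_map, pathway_sets)
        io.write_table(edges, out / "network_edges.tsv")
        manifest["stages"]["network"] = {"edges": len(edges)}

    if config.catalog:
        catalog = io.read_catalog_tsv(config.catalog)
        trait_map = io.read_table(config.trait_map, dtype=str) if config.trait_map else None
        combined = pd.concat([meta_exact, meta_cat], ignore_index=True)
        annot = match_catalog(combined, catalog, trait_map=trait_map, p_max=thr.catalog_p)
        io.write_table(annot, out / "catalog_annotation.tsv")
        manifest["stages"]["catalog"] = {
            "annotated": len(annot),
            "previously_reported": int((annot["status"] == "previously reported").sum()),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
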