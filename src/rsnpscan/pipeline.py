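"""End-to-end orchestration of the rSNP analysis.

Stage order mirrors the analysis flow: DEG filtering, promoter extraction,
TFBS enrichment per tissue, SNP-to-promoter assignment, allele-swap
consequence classification, Boruta consensus on rSNP genotypes, DEG/rSNP
joins, and TSS-relative position histograms.  Every stage writes its table
under the output directory and a manifest records versions, the seed, a
parameter hash and the record-count funnel, so any output can be reproduced
exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, association, deg, enrichment, io_formats, promoters, rsnp
from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run (YAML-loadable)."""

    genome: str
    gff: str
    vcf: str
    pfm: str
    deg_tables: dict[str, str]  # tissue -> TSV path
    genotypes: str
    labels: str
    outdir: str
    seed: int = 0
    promoter_up: int = 500
    promoter_down: int = 100
    maf_threshold: float = 0.05
    mss_threshold: float = 0.85
    flank: int = 25
    deg_lfc: float = 2.0
    deg_alpha: float = 0.05
    enrich_alpha: float = 0.01
    bg_ratio: int = 1
    gc_bin_width: float = 0.05
    boruta_runs: int = 20
    boruta_trees: int = 500
    boruta_max_iter: int = 100
    boruta_max_depth: int | None = association.DEFAULT_MAX_DEPTH
    hist_bin_width: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("genome", "gff", "vcf", "pfm", "genotypes", "labels"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ParameterError(f"config path {name}={path!r} does not exist")
        for tissue, path in self.deg_tables.items():
            if not Path(path).exists():
                raise ParameterError(f"DEG table for {tissue!r}: {path!r} missing")
        if not 0 < self.mss_threshold <= 1:
            raise ParameterError("mss_threshold must be in (0, 1]")
        if self.flank < 1:
            raise ParameterError("flank must be >= 1")

    def param_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(seed: int, stage: int) -> int:
    """Per-stage seed derived from the global seed (documented derivation:
    entry ``stage`` of SeedSequence(seed).spawn, folded below 2**31)."""
    ss = np.random.SeedSequence(seed)
    return int(ss.spawn(stage + 1)[stage].generate_state(1)[0] % (2**31 - 1))


def _write(table: pd.DataFrame, path: Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a summary dict (also written as manifest.json).

    Any stage failure propagates with the stage name prepended; outputs of
    completed stages remain on disk.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    funnel: dict[str, int] = {}
    stage = "load"
    try:
        genome = io_formats.read_fasta(config.genome)
        genes = io_formats.read_gff3(config.gff)
        snps = io_formats.read_vcf(config.vcf, genome=genome)
        funnel["snps_in"] = len(snps)
        snps = io_formats.filter_maf(snps, threshold=config.maf_threshold)
        funnel["snps_maf_pass"] = len(snps)
        pwms = io_formats.read_jaspar_pfm(config.pfm)
        funnel["pwms"] = len(pwms)
        logger.info("loaded %d genes, %d SNPs, %d PWMs", len(genes), len(snps), len(pwms))

        stage = "filter-degs"
        deg_sets: dict[str, set[str]] = {}
        deg_rows = []
        for tissue, path in config.deg_tables.items():
            table = io_formats.read_deg_table(path)
            up, down = deg.filter_degs(table, lfc=config.deg_lfc, alpha=config.deg_alpha)
            deg_sets[tissue] = up | down
            deg_rows += [
                {"tissue": tissue, "gene": g, "direction": "up"} for g in sorted(up)
            ] + [
                {"tissue": tissue, "gene": g, "direction": "down"} for g in sorted(down)
            ]
            funnel[f"degs_{tissue}"] = len(up) + len(down)
        _write(pd.DataFrame(deg_rows, columns=["tissue", "gene", "direction"]),
               outdir / "degs.tsv")

        stage = "promoters"
        regions = promoters.promoter_regions(
            genes, genome, up=config.promoter_up, down=config.promoter_down
        )
        region_by_gene = {r.gene_id: r for r in regions}
        promoter_seqs = {
            r.gene_id: promoters.extract_promoter_sequence(genome, r) for r in regions
        }
        bed = pd.DataFrame(
            [
                {
                    "chrom": r.chromosome,
                    "start": r.abs_start,
                    "end": r.abs_end,
                    "gene_id": r.gene_id,
                    "score": ".",
                    "strand": r.strand,
                }
                for r in regions
            ]
        )
        _write(bed, outdir / "promoters.bed")

        stage = "enrich"
        all_genes = sorted(promoter_seqs)
        enrich_rows = []
        for i, (tissue, fg_genes) in enumerate(sorted(deg_sets.items())):
            fg = sorted(g for g in fg_genes if g in promoter_seqs)
            candidates = [g for g in all_genes if g not in fg_genes]
            bg = enrichment.select_background(
                fg,
                candidates,
                promoter_seqs,
                ratio=config.bg_ratio,
                bin_width=config.gc_bin_width,
                seed=stage_seed(config.seed, 10 + i),
            )
            fg_matrix = enrichment.tfbs_presence(
                {g: promoter_seqs[g] for g in fg}, pwms, threshold=config.mss_threshold
            )
            bg_matrix = enrichment.tfbs_presence(
                {g: promoter_seqs[g] for g in bg}, pwms, threshold=config.mss_threshold
            )
            results = enrichment.enrich(fg_matrix, bg_matrix, pwms, alpha=config.enrich_alpha)
            for r in results:
                row = vars(r).copy()
                row["tissue"] = tissue
                enrich_rows.append(row)
            funnel[f"enriched_{tissue}"] = sum(r.enriched for r in results)
        _write(pd.DataFrame(enrich_rows), outdir / "enrichment.tsv")

        stage = "assign-snps"
        assignments = promoters.assign_snps_to_promoters(snps, regions)
        funnel["promoter_snp_assignments"] = len(assignments)
        promoter_snp_ids = {a.snp_id for a in assignments}
        promoter_snps = [s for s in snps if s.id in promoter_snp_ids]
        funnel["promoter_snps"] = len(promoter_snps)

        stage = "classify"
        records = rsnp.classify_snps(
            genome,
            promoter_snps,
            pwms,
            threshold=config.mss_threshold,
            k=config.flank,
        )
        rsnps = rsnp.call_rsnps(records)
        funnel["consequence_records"] = len(records)
        funnel["rsnps"] = len(rsnps)
        snp_by_id = {s.id: s for s in promoter_snps}
        offset_by_pair = {(a.snp_id, a.gene_id): a.offset for a in assignments}
        gene_of = {}
        for a in assignments:
            gene_of.setdefault(a.snp_id, []).append(a.gene_id)
        cons_rows = []
        for rec in records:
            for gene_id in gene_of.get(rec.snp_id, [None]):
                s = snp_by_id[rec.snp_id]
                cons_rows.append(
                    {
                        "snp_id": rec.snp_id,
                        "chrom": s.chromosome,
                        "pos": s.pos,
                        "ref": s.ref,
                        "alt": s.alt,
                        "gene_id": gene_id,
                        "offset_to_tss": offset_by_pair.get((rec.snp_id, gene_id)),
                        "matrix_id": rec.matrix_id,
                        "tf_name": rec.tf_name,
                        "site_start": rec.site_start,
                        "strand": rec.strand,
                        "mss_ref": rec.mss_ref,
                        "mss_alt": rec.mss_alt,
                        "consequence": rec.consequence.value,
                    }
                )
        cons_table = pd.DataFrame(
            cons_rows,
            columns=[
                "snp_id", "chrom", "pos", "ref", "alt", "gene_id", "offset_to_tss",
                "matrix_id", "tf_name", "site_start", "strand", "mss_ref", "mss_alt",
                "consequence",
            ],
        ).sort_values(["snp_id", "gene_id", "matrix_id", "site_start", "strand"])
        _write(cons_table, outdir / "consequences.tsv")
        rsnp_positions = rsnp.annotate_rsnp_positions(rsnps, assignments)
        _write(rsnp_positions.sort_values(["snp_id", "gene_id"]), outdir / "rsnp_positions.tsv")

        stage = "select"
        genotypes, labels = association.load_genotypes(config.genotypes, config.labels)
        geno_rsnps = [c for c in genotypes.columns if c in rsnps]
        funnel["rsnps_with_genotypes"] = len(geno_rsnps)
        if geno_rsnps:
            important = association.consensus_important(
                genotypes.loc[:, geno_rsnps],
                labels,
                n_runs=config.boruta_runs,
                base_seed=stage_seed(config.seed, 20),
                max_iter=config.boruta_max_iter,
                n_trees=config.boruta_trees,
                max_depth=config.boruta_max_depth,
            )
        else:
            important = set()
        funnel["important_rsnps"] = len(important)
        _write(
            pd.DataFrame({"snp_id": sorted(important)}), outdir / "important_rsnps.tsv"
        )

        stage = "join"
        rsnp_gene_map = rsnp_positions
        per_tissue = deg.degs_with_rsnps(deg_sets, rsnp_gene_map)
        for tissue, table in per_tissue.items():
            _write(table, outdir / f"degs_with_rsnps_{tissue}.tsv")
            funnel[f"degs_with_rsnps_{tissue}"] = len(table)
        imp_tissue = deg.important_rsnps_per_tissue(important, rsnp_gene_map, deg_sets)
        for tissue, table in imp_tissue.items():
            _write(table, outdir / f"important_rsnps_{tissue}.tsv")
            funnel[f"important_rsnps_{tissue}"] = table["snp_id"].nunique()
        if len(deg_sets) >= 2:
            venn = deg.venn_counts(deg_sets)
            _write(
                pd.DataFrame(
                    [{"region": "&".join(k), "count": v} for k, v in sorted(venn.items())]
                ),
                outdir / "deg_venn.tsv",
            )

        stage = "histograms"
        for name, id_set in (("rsnp", rsnps), ("important", important)):
            kept = [a for a in assignments if a.snp_id in id_set]
            edges, counts = promoters.position_histogram(
                kept,
                bin_width=config.hist_bin_width,
                up=config.promoter_up,
                down=config.promoter_down,
            )
            _write(
                pd.DataFrame(
                    {
                        "bin_start": edges[:-1],
                        "bin_end": edges[1:],
                        "count": counts,
                    }
                ),
                outdir / f"position_histogram_{name}.tsv",
            )
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "config": dataclasses.asdict(config),
        "funnel": funnel,
    }
    with open(outdir / "manifest.json", "w") as out:
        json.dump(manifest, out, indent=2, sort_keys=True)
    return manifest
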