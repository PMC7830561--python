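"""Synthetic fixture generator with planted, verifier-guaranteed truth.

Produces an internally consistent miniature data set with the same structure
the analysis assumes: a random genome with genes on both strands, a small
PWM library with sharp base preferences, promoter SNPs planted so that the
package's own scanner provably calls them Gain-of-TFBS, Loss-of-TFBS or
neither, class-differentiated genotypes under Hardy-Weinberg for two
cultivar groups, and per-tissue differential-expression tables with planted
up/down genes.

Every planted consequence is validated against the actual scanning and
classification code at generation time (with bounded retries), so the truth
labels downstream recovery tests rely on are exact, not probabilistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RsnpScanError
from . import io_formats, motif_scan, rsnp as rsnp_mod
from .io_formats import BASES, PWM, GeneModel, SnpRecord, pwm_from_counts
from .promoters import promoter_regions

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "simulate_genome_and_genes",
    "generate_pfm_counts",
    "plant_snp_consequences",
    "simulate_genotypes",
    "simulate_deg_tables",
    "simulate_all",
]


@dataclass
class SimulationConfig:
    """Study-condition parameters for one synthetic data set."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 150_000
    gc: float = 0.37  # Brassica-like genomic GC
    n_genes: int = 60
    promoter_up: int = 500
    promoter_down: int = 100
    n_pwms: int = 8
    motif_length_range: tuple[int, int] = (6, 10)
    n_gain: int = 50
    n_loss: int = 50
    n_neutral: int = 100
    mss_threshold: float = 0.85
    flank: int = 25
    n_samples_per_class: tuple[int, int] = (100, 100)
    n_associated: int = 5
    delta: float = 0.4  # between-class alt-allele frequency difference
    tissues: tuple[str, ...] = ("flower", "leaf", "stem", "root")
    n_up: int = 10
    n_down: int = 10
    deg_overlap: float = 0.3  # fraction of planted DEGs shared by all tissues
    maf_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise RsnpScanError("delta must be in [0, 1]")
        if min(self.n_gain, self.n_loss, self.n_neutral) < 0:
            raise RsnpScanError("planted counts must be non-negative")


# ---------------------------------------------------------------------------
# genome + genes
# ---------------------------------------------------------------------------

def simulate_genome_and_genes(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome at the configured GC with non-overlapping genes.

    Gene footprints (gene body plus promoter margin) are kept disjoint and
    promoters lie fully inside their chromosome, so no promoter window is
    ever clipped.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    g = config.gc
    probs = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
    genome = {}
    chrom_names = [f"chr{c + 1:02d}" for c in range(config.n_chromosomes)]
    for name in chrom_names:
        codes = rng.choice(4, size=config.chromosome_length, p=probs)
        genome[name] = "".join(BASES[c] for c in codes)

    up, down = config.promoter_up, config.promoter_down
    genes: list[GeneModel] = []
    per_chrom = -(-config.n_genes // config.n_chromosomes)  # ceil
    gi = 0
    for name in chrom_names:
        cursor = up + 10  # leave room for the first promoter
        placed = 0
        while placed < per_chrom and gi < config.n_genes:
            gene_len = int(rng.integers(500, 1500))
            gap = int(rng.integers(100, 400))
            strand = "+" if rng.random() < 0.5 else "-"
            start = cursor + (up if strand == "+" else 0) + 1  # 1-based
            end = start + gene_len - 1
            margin_end = end + (up if strand == "-" else down)
            if margin_end + 10 > config.chromosome_length:
                break
            genes.append(
                GeneModel(
                    gene_id=f"gene{gi + 1:04d}",
                    chromosome=name,
                    strand=strand,
                    start=start,
                    end=end,
                )
            )
            cursor = margin_end + gap
            placed += 1
            gi += 1
    if gi < config.n_genes:
        raise RsnpScanError(
            f"placed only {gi}/{config.n_genes} genes; increase chromosome_length"
        )
    return genome, genes


# ---------------------------------------------------------------------------
# PWM library
# ---------------------------------------------------------------------------

def generate_pfm_counts(
    config: SimulationConfig,
) -> list[tuple[str, str, np.ndarray]]:
    """Synthetic JASPAR-style count matrices with one dominant base per column.

    Column counts total 100 with the dominant base at 80-95, giving sharp,
    scoreable motifs comparable to curated plant PFMs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    lo, hi = config.motif_length_range
    out = []
    for m in range(config.n_pwms):
        L = int(rng.integers(lo, hi + 1))
        counts = np.zeros((L, 4), dtype=int)
        for i in range(L):
            dom = int(rng.integers(4))
            dom_count = int(rng.integers(80, 96))
            rest = 100 - dom_count
            others = rng.multinomial(rest, [1 / 3] * 3)
            row = list(others[:dom]) + [dom_count] + list(others[dom:])
            counts[i] = row
        out.append((f"MX{m + 1:04d}", f"TF{m + 1:02d}", counts))
    return out


# ---------------------------------------------------------------------------
# planting SNP consequences
# ---------------------------------------------------------------------------

def _column_contributions(pwm: PWM) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-column information-weighted frequencies, spans, and total span."""
    info = motif_scan.information_vector(pwm)
    weighted = info[:, None] * pwm.freqs
    spans = weighted.max(axis=1) - weighted.min(axis=1)
    return weighted, spans, float(spans.sum())


def _design_planted_word(
    pwm: PWM, rng: np.random.Generator
) -> tuple[str, int, str, str] | None:
    """Design a planted site word for a gain/loss event.

    Returns (base word, SNP column j, strong base, weak base) such that the
    word with the strong base at j scores >= 0.86 and with the weak base
    scores <= 0.84, or None when the matrix cannot support a threshold
    crossing.  The base word may carry deliberate mismatches at other
    columns so the pair straddles the 0.85 threshold.
    """
    weighted, spans, total = _column_contributions(pwm)
    if total <= 0:
        return None
    L = len(pwm)
    contrib = spans / total  # per-column share of the min-max span
    j = int(np.argmax(contrib))
    c_j = float(contrib[j])
    lo_target, hi_target = max(0.0, 0.16 - c_j), 0.14
    if c_j < 0.03 or lo_target > hi_target:
        return None

    # penalty options: (cost, column, base) for non-argmax bases elsewhere
    argmax = np.argmax(pwm.freqs, axis=1)
    options = []
    for i in range(L):
        if i == j:
            continue
        for b in range(4):
            if b == argmax[i]:
                continue
            cost = float((weighted[i].max() - weighted[i, b]) / total)
            options.append((cost, i, b))
    options.sort()

    chosen: dict[int, int] = {}
    penalty = 0.0
    for cost, i, b in options:
        if penalty >= lo_target:
            break
        if i in chosen or penalty + cost > hi_target:
            continue
        chosen[i] = b
        penalty += cost
    if penalty < lo_target:
        return None

    word = [BASES[argmax[i]] for i in range(L)]
    for i, b in chosen.items():
        word[i] = BASES[b]
    strong = BASES[argmax[j]]
    weak = BASES[int(np.argmin(weighted[j]))]
    # confirm with the real scorer
    w_strong = "".join(word[:j]) + strong + "".join(word[j + 1 :])
    w_weak = "".join(word[:j]) + weak + "".join(word[j + 1 :])
    if motif_scan.mss(pwm, w_strong) < 0.86 or motif_scan.mss(pwm, w_weak) > 0.84:
        return None
    return "".join(word), j, strong, weak


def _verify_consequence(
    genome: dict[str, str],
    snp: SnpRecord,
    pwms: list[PWM],
    config: SimulationConfig,
    expect: str,
) -> bool:
    """Run the real classifier and check the planted truth label."""
    records = rsnp_mod.classify_snps(
        genome,
        [snp],
        pwms,
        threshold=config.mss_threshold,
        k=config.flank,
    )
    called = snp.id in rsnp_mod.call_rsnps(records)
    if expect == "neutral":
        return not called
    if not called:
        return False
    kinds = {r.consequence for r in records}
    want = (
        rsnp_mod.Consequence.GAIN_OF_TFBS
        if expect == "gain"
        else rsnp_mod.Consequence.LOSS_OF_TFBS
    )
    return want in kinds


def plant_snp_consequences(
    genome: dict[str, str],
    genes: list[GeneModel],
    pwms: list[PWM],
    config: SimulationConfig,
    max_retries: int = 200,
) -> tuple[dict[str, str], list[SnpRecord], pd.DataFrame]:
    """Plant gain/loss/neutral SNPs in promoters, verifying with the scanner.

    Gain SNPs get a designed motif word embedded in the genome whose weak
    (reference) allele scores below the MSS threshold while the alternate
    allele scores above it; loss SNPs are the mirror image (strong allele in
    the genome).  Neutral SNPs are plain promoter substitutions checked to
    produce no Gain/Loss against the whole library.  Returns the mutated
    genome, the SNP list and a truth table; every label is re-verified with
    the production classifier before return.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    chrom_arrays = {name: bytearray(seq, "ascii") for name, seq in genome.items()}
    regions = promoter_regions(
        genes, genome, up=config.promoter_up, down=config.promoter_down
    )
    max_L = max(len(p) for p in pwms)
    guard = config.flank + max_L + 1
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}

    def is_free(chrom: str, start: int, end: int) -> bool:
        return all(e <= start - guard or s >= end + guard for s, e in occupied[chrom])

    def current_genome() -> dict[str, str]:
        return {name: arr.decode("ascii") for name, arr in chrom_arrays.items()}

    snps: list[SnpRecord] = []
    truth_rows: list[dict] = []
    n_snp = 0

    plan = [("gain", config.n_gain), ("loss", config.n_loss), ("neutral", config.n_neutral)]
    for kind, count in plan:
        planted = 0
        attempts = 0
        while planted < count:
            attempts += 1
            if attempts > max_retries * max(count, 1):
                raise RsnpScanError(
                    f"could not place {kind} SNP {planted + 1}/{count} "
                    f"after {attempts} attempts"
                )
            region = regions[int(rng.integers(len(regions)))]
            chrom = region.chromosome
            if kind in ("gain", "loss"):
                pwm = pwms[int(rng.integers(len(pwms)))]
                design = _design_planted_word(pwm, rng)
                if design is None:
                    continue
                word, j, strong, weak = design
                L = len(word)
                if len(region) < L:
                    continue
                site_start = region.abs_start + int(rng.integers(len(region) - L + 1))
                pos0 = site_start + j
                if not is_free(chrom, site_start, site_start + L):
                    continue
                if pos0 - config.flank < 0 or pos0 + config.flank >= len(
                    chrom_arrays[chrom]
                ):
                    continue
                genome_base = strong if kind == "loss" else weak
                alt_base = weak if kind == "loss" else strong
                embedded = word[:j] + genome_base + word[j + 1 :]
                backup = bytes(chrom_arrays[chrom][site_start : site_start + L])
                chrom_arrays[chrom][site_start : site_start + L] = embedded.encode()
                snp = SnpRecord(
                    id=f"snp{n_snp + 1:05d}",
                    chromosome=chrom,
                    pos=pos0 + 1,
                    ref=genome_base,
                    alt=alt_base,
                    maf=round(float(rng.uniform(0.06, 0.5)), 6),
                )
                if not _verify_consequence(current_genome(), snp, pwms, config, kind):
                    chrom_arrays[chrom][site_start : site_start + L] = backup
                    continue
                occupied[chrom].append((site_start, site_start + L))
                matrix_id = pwm.matrix_id
            else:
                pos0 = region.abs_start + int(rng.integers(len(region)))
                if not is_free(chrom, pos0, pos0 + 1):
                    continue
                if pos0 - config.flank < 0 or pos0 + config.flank >= len(
                    chrom_arrays[chrom]
                ):
                    continue
                ref_base = chr(chrom_arrays[chrom][pos0])
                if ref_base not in BASES:
                    continue
                alt_base = str(
                    rng.choice([b for b in BASES if b != ref_base])
                )
                snp = SnpRecord(
                    id=f"snp{n_snp + 1:05d}",
                    chromosome=chrom,
                    pos=pos0 + 1,
                    ref=ref_base,
                    alt=alt_base,
                    maf=round(float(rng.uniform(0.06, 0.5)), 6),
                )
                if not _verify_consequence(current_genome(), snp, pwms, config, kind):
                    continue
                occupied[chrom].append((pos0, pos0 + 1))
                matrix_id = ""
            snps.append(snp)
            truth_rows.append(
                {
                    "snp_id": snp.id,
                    "chrom": snp.chromosome,
                    "pos": snp.pos,
                    "ref": snp.ref,
                    "alt": snp.alt,
                    "gene_id": region.gene_id,
                    "planted": kind,
                    "matrix_id": matrix_id,
                }
            )
            planted += 1
            n_snp += 1

    final = current_genome()
    for row, snp in zip(truth_rows, snps):
        if not _verify_consequence(final, snp, pwms, config, row["planted"]):
            raise RsnpScanError(
                f"post-hoc verification failed for {snp.id} ({row['planted']}); "
                "guard spacing too small"
            )
    truth = pd.DataFrame(truth_rows)
    return final, snps, truth


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    config: SimulationConfig,
    snp_ids: list[str],
    associated_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Hardy-Weinberg genotypes for two cultivar groups.

    Non-associated SNPs share one alt-allele frequency drawn from
    U(0.1, 0.5) across both classes; associated SNPs differ by ``delta``
    between classes (clipped into (0.05, 0.95) with a warning).  The
    empirical MAF of every column is kept above the configured threshold by
    resampling.  Returns (genotypes, labels, associated ids).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    n0, n1 = config.n_samples_per_class
    n = n0 + n1
    labels = pd.Series(
        ["high_oil"] * n0 + ["low_oil"] * n1,
        index=[f"s{i + 1:04d}" for i in range(n)],
        name="cultivar",
    )
    if associated_ids is None:
        k = min(config.n_associated, len(snp_ids))
        associated_ids = [str(s) for s in rng.choice(snp_ids, size=k, replace=False)]
    assoc = set(associated_ids)

    data = np.zeros((n, len(snp_ids)), dtype=int)
    for j, snp_id in enumerate(snp_ids):
        for _ in range(100):
            if snp_id in assoc:
                f0 = float(rng.uniform(0.1, 0.5))
                f1 = f0 + config.delta
                if f1 >= 0.95:
                    f1 = 0.95
                    logger.warning("%s: class frequency clipped to 0.95", snp_id)
            else:
                f0 = f1 = float(rng.uniform(0.1, 0.5))
            col = np.concatenate(
                [rng.binomial(2, f0, size=n0), rng.binomial(2, f1, size=n1)]
            )
            af = col.sum() / (2 * n)
            if min(af, 1 - af) > config.maf_threshold:
                data[:, j] = col
                break
        else:
            raise RsnpScanError(f"{snp_id}: cannot satisfy MAF constraint")
    genotypes = pd.DataFrame(data, index=labels.index, columns=snp_ids)
    return genotypes, labels, associated_ids


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

def simulate_deg_tables(
    config: SimulationConfig,
    gene_ids: list[str],
) -> tuple[dict[str, pd.DataFrame], dict[str, tuple[set[str], set[str]]]]:
    """Per-tissue DE result tables with planted up/down genes.

    Planted genes get |log2FC| in (2.5, 6) and padj in (1e-8, 1e-3); null
    genes get |log2FC| < 2 with a mix of small and non-significant padj
    (plus a few padj = NA rows).  A ``deg_overlap`` fraction of planted
    genes is shared across all tissues.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    n_shared_up = int(round(config.deg_overlap * config.n_up))
    n_shared_down = int(round(config.deg_overlap * config.n_down))
    need = config.n_up + config.n_down
    if need > len(gene_ids):
        raise RsnpScanError("more planted DEGs than genes")

    shuffled = list(rng.permutation(gene_ids))
    shared_up = shuffled[:n_shared_up]
    shared_down = shuffled[n_shared_up : n_shared_up + n_shared_down]
    remainder = shuffled[n_shared_up + n_shared_down :]

    tables: dict[str, pd.DataFrame] = {}
    truth: dict[str, tuple[set[str], set[str]]] = {}
    n_extra_up = config.n_up - n_shared_up
    n_extra_down = config.n_down - n_shared_down
    if n_extra_up + n_extra_down > len(remainder):
        raise RsnpScanError("gene pool exhausted; increase n_genes")
    for tissue in config.tissues:
        # tissue-specific DEGs come from the shared non-core pool; overlap
        # between tissues beyond the planted core is incidental
        extra = list(
            rng.choice(remainder, size=n_extra_up + n_extra_down, replace=False)
        )
        up = set(shared_up) | set(extra[:n_extra_up])
        down = set(shared_down) | set(extra[n_extra_up:])

        rows = []
        for gene in gene_ids:
            if gene in up or gene in down:
                lfc = float(rng.uniform(2.5, 6.0))
                if gene in down:
                    lfc = -lfc
                padj = float(10 ** rng.uniform(-8, -3))
            else:
                lfc = float(rng.uniform(-1.8, 1.8))
                padj = float(rng.uniform(0.05, 1.0)) if rng.random() < 0.7 else float(
                    rng.uniform(0.0, 0.05)
                )
                if rng.random() < 0.05:
                    padj = np.nan
            rows.append({"gene": gene, "log2FoldChange": lfc, "padj": padj})
        tables[tissue] = pd.DataFrame(rows)
        truth[tissue] = (up, down)
    return tables, truth


# ---------------------------------------------------------------------------
# one-call fixture bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """All in-memory pieces of one simulated study."""

    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    pwms: list[PWM]
    pfm_counts: list[tuple[str, str, np.ndarray]]
    snps: list[SnpRecord]
    truth: pd.DataFrame
    genotypes: pd.DataFrame
    labels: pd.Series
    associated: list[str]
    deg_tables: dict[str, pd.DataFrame]
    deg_truth: dict[str, tuple[set[str], set[str]]]


def simulate_all(config: SimulationConfig, outdir: str | Path | None = None) -> SyntheticDataset:
    """Generate a full consistent data set; optionally write it to disk.

    The written bundle comprises genome.fa, genes.gff3, snps.vcf,
    motifs.pfm, genotypes.tsv, labels.tsv, deg_<tissue>.tsv and the truth
    tables.  Same seed, same bytes.
    """
    genome0, genes = simulate_genome_and_genes(config)
    pfm_counts = generate_pfm_counts(config)
    pwms = [pwm_from_counts(mid, name, counts) for mid, name, counts in pfm_counts]
    genome, snps, truth = plant_snp_consequences(genome0, genes, pwms, config)
    rsnp_ids = list(truth.loc[truth["planted"] != "neutral", "snp_id"])
    genotypes, labels, associated = simulate_genotypes(config, rsnp_ids)
    gene_ids = [g.gene_id for g in genes]
    deg_tables, deg_truth = simulate_deg_tables(config, gene_ids)

    ds = SyntheticDataset(
        config=config,
        genome=genome,
        genes=genes,
        pwms=pwms,
        pfm_counts=pfm_counts,
        snps=snps,
        truth=truth,
        genotypes=genotypes,
        labels=labels,
        associated=associated,
        deg_tables=deg_tables,
        deg_truth=deg_truth,
    )
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_formats.write_fasta(ds.genome, outdir / "genome.fa")
    io_formats.write_gff3(ds.genes, outdir / "genes.gff3")
    io_formats.write_vcf(
        ds.snps, outdir / "snps.vcf", {c: len(s) for c, s in ds.genome.items()}
    )
    io_formats.write_jaspar_pfm(ds.pfm_counts, outdir / "motifs.pfm")
    ds.truth.to_csv(outdir / "truth_snps.tsv", sep="\t", index=False)
    ds.genotypes.to_csv(outdir / "genotypes.tsv", sep="\t", index_label="sample")
    ds.labels.to_frame().to_csv(outdir / "labels.tsv", sep="\t", index_label="sample")
    pd.DataFrame({"snp_id": ds.associated}).to_csv(
        outdir / "truth_associated.tsv", sep="\t", index=False
    )
    for tissue, table in ds.deg_tables.items():
        io_formats.write_deg_table(table, outdir / f"deg_{tissue}.tsv")
    rows = []
    for tissue, (up, down) in ds.deg_truth.items():
        rows += [{"tissue": tissue, "gene": g, "direction": "up"} for g in sorted(up)]
        rows += [
            {"tissue": tissue, "gene": g, "direction": "down"} for g in sorted(down)
        ]
    pd.DataFrame(rows).to_csv(outdir / "truth_degs.tsv", sep="\t", index=False)
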