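"""Readers and writers for the external formats the pipeline touches.

External formats keep their native coordinate conventions (VCF and GFF3 are
1-based inclusive); everything downstream of the I/O boundary uses 0-based
half-open intervals.  Conversions happen exactly once, here or in
:mod:`rsnpscan.promoters`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO, motifs

from .errors import DataIntegrityError, FormatError

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: default pseudo-frequency added to PFM-derived frequencies before renormalizing
DEFAULT_PSEUDOCOUNT = 1e-4

__all__ = [
    "GenomeSequences",
    "GeneModel",
    "SnpRecord",
    "PWM",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_vcf",
    "write_vcf",
    "filter_maf",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "pwm_from_counts",
    "read_deg_table",
    "write_deg_table",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

#: mapping chromosome name -> uppercase sequence over {A,C,G,T,N}
GenomeSequences = dict


@dataclass(frozen=True)
class GeneModel:
    """A gene feature from a GFF3 annotation (1-based inclusive coords)."""

    gene_id: str
    chromosome: str
    strand: str  # '+' or '-'
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise FormatError(
                f"gene {self.gene_id}: invalid interval {self.start}-{self.end}"
            )


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNV with 1-based position and optional minor-allele frequency."""

    id: str
    chromosome: str
    pos: int
    ref: str
    alt: str
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise FormatError(f"SNP {self.id}: alleles must be single ACGT bases")
        if self.ref == self.alt:
            raise FormatError(f"SNP {self.id}: ref equals alt ({self.ref})")
        if self.maf is not None and not 0.0 < self.maf <= 0.5:
            raise FormatError(f"SNP {self.id}: MAF {self.maf} outside (0, 0.5]")


@dataclass(frozen=True)
class PWM:
    """A position weight matrix as per-position base frequencies.

    ``freqs`` has shape (L, 4) in A,C,G,T order; every row sums to 1 and all
    entries are strictly positive (pseudocount applied at construction), so
    the information-vector logarithms downstream are always finite.
    """

    matrix_id: str
    tf_name: str
    freqs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4 or f.shape[0] < 1:
            raise FormatError(f"{self.matrix_id}: frequency matrix must be (L, 4)")
        if not np.all(f > 0):
            raise FormatError(f"{self.matrix_id}: frequencies must be strictly positive")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise FormatError(f"{self.matrix_id}: columns must sum to 1")
        object.__setattr__(self, "freqs", f)

    def __len__(self) -> int:
        return self.freqs.shape[0]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequences:
    """Read a FASTA file into ``{name: uppercase sequence}``.

    Lowercase input is accepted and uppercased; any base outside {A,C,G,T,N}
    is an error.  Duplicate headers and empty sequences are format errors.
    """
    path = Path(path)
    genome: GenomeSequences = {}
    with open(path) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    for rec in records:
        if rec.id in genome:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: sequence {rec.id!r} is empty")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise FormatError(
                f"{path}: sequence {rec.id!r} contains invalid characters {sorted(bad)}"
            )
        genome[rec.id] = seq
    return genome


def write_fasta(genome: GenomeSequences, path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA with fixed line wrapping (round-trip safe)."""
    with open(path, "w") as out:
        for name, seq in genome.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file, returning only ``gene`` features.

    ``gene_id`` is taken from the ``ID`` attribute; a missing ID is a format
    error.  Features with strand '.' are skipped with a warning (promoter
    geometry is undefined without orientation).
    """
    import gffutils

    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises assorted internal errors
        raise FormatError(f"{path}: cannot parse GFF3 ({exc})") from exc
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        if "ID" not in feat.attributes:
            raise FormatError(f"{path}: gene feature at {feat.seqid}:{feat.start} lacks ID")
        gene_id = feat.attributes["ID"][0]
        if feat.strand not in "+-":
            warnings.warn(
                f"gene {gene_id}: strand {feat.strand!r} unknown; record skipped"
            )
            continue
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for g in genes:
            out.write(
                f"{g.chromosome}\trsnpscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _maf_from_genotypes(record: "pysam.VariantRecord", alt_index: int) -> float | None:
    """Allele frequency of ``alt_index`` folded to the minor allele, from GT calls."""
    n_alt = 0
    n_total = 0
    for sample in record.samples.values():
        gt = sample.get("GT")
        if gt is None:
            continue
        for allele in gt:
            if allele is None:
                continue
            n_total += 1
            if allele == alt_index:
                n_alt += 1
    if n_total == 0:
        return None
    af = n_alt / n_total
    return min(af, 1.0 - af)


def read_vcf(path: str | Path, genome: GenomeSequences | None = None) -> list[SnpRecord]:
    """Read a VCF into biallelic :class:`SnpRecord` objects.

    Multi-allelic records are split into one record per ALT; indels and
    non-ACGT alleles are dropped.  MAF comes from the ``MAF`` INFO field when
    present, else is computed from genotype columns, else is left ``None``.
    When ``genome`` is supplied, a REF allele disagreeing with the genome
    base is a data-integrity error naming the site.
    """
    path = Path(path)
    snps: list[SnpRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref = (rec.ref or "").upper()
            if ref not in BASES:
                continue
            if genome is not None:
                if rec.chrom not in genome:
                    raise DataIntegrityError(
                        f"{path}: chromosome {rec.chrom!r} not in genome"
                    )
                genome_base = genome[rec.chrom][rec.pos - 1]
                if genome_base != ref:
                    raise DataIntegrityError(
                        f"{path}: REF mismatch at {rec.chrom}:{rec.pos} "
                        f"(VCF {ref}, genome {genome_base})"
                    )
            info_maf = rec.info.get("MAF") if "MAF" in rec.info else None
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                alt = alt.upper()
                if alt not in BASES:
                    continue
                if info_maf is not None:
                    maf = round(float(info_maf), 6)  # pysam stores Float32
                else:
                    maf = _maf_from_genotypes(rec, alt_index)
                snp_id = rec.id or f"{rec.chrom}_{rec.pos}_{ref}_{alt}"
                if len(rec.alts or ()) > 1:
                    snp_id = f"{snp_id}_{alt}" if rec.id else snp_id
                snps.append(
                    SnpRecord(
                        id=snp_id,
                        chromosome=rec.chrom,
                        pos=rec.pos,
                        ref=ref,
                        alt=alt,
                        maf=maf,
                    )
                )
    return snps


def write_vcf(
    snps: Sequence[SnpRecord],
    path: str | Path,
    contig_lengths: Mapping[str, int],
) -> None:
    """Write sites-only VCF 4.2 with MAF in INFO."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for name, length in contig_lengths.items():
            out.write(f"##contig=<ID={name},length={length}>\n")
        out.write(
            '##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n'
        )
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snps, key=lambda s: (s.chromosome, s.pos)):
            info = f"MAF={s.maf:.6g}" if s.maf is not None else "."
            out.write(
                f"{s.chromosome}\t{s.pos}\t{s.id}\t{s.ref}\t{s.alt}\t.\t.\t{info}\n"
            )


def filter_maf(snps: Iterable[SnpRecord], threshold: float = 0.05) -> list[SnpRecord]:
    """Keep SNPs with MAF strictly greater than ``threshold``.

    The boundary is exclusive: a SNP at exactly the threshold is removed.
    A SNP without a populated MAF cannot be filtered and is an error.
    """
    out = []
    for snp in snps:
        if snp.maf is None:
            raise DataIntegrityError(
                f"SNP {snp.id}: MAF missing; supply genotypes or an MAF INFO field"
            )
        if snp.maf > threshold:
            out.append(snp)
    return out


# ---------------------------------------------------------------------------
# JASPAR PFMs
# ---------------------------------------------------------------------------

def pwm_from_counts(
    matrix_id: str,
    tf_name: str,
    counts: np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PWM:
    """Convert a (L, 4) count matrix to a PWM.

    Counts are divided by their per-position sum, the pseudo-frequency is
    added to every entry, and rows are renormalized to sum to 1.  This keeps
    every frequency strictly positive without materially shifting the
    observed base preferences.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise FormatError(f"{matrix_id}: count matrix must be (L, 4)")
    if np.any(counts < 0):
        raise FormatError(f"{matrix_id}: negative counts")
    col_sums = counts.sum(axis=1)
    if np.any(col_sums <= 0):
        raise FormatError(f"{matrix_id}: zero-sum count column")
    freqs = counts / col_sums[:, None] + pseudocount
    freqs /= freqs.sum(axis=1)[:, None]
    return PWM(matrix_id=matrix_id, tf_name=tf_name, freqs=freqs)


def read_jaspar_pfm(
    path: str | Path, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> list[PWM]:
    """Read JASPAR-format PFMs (``>ID name`` header then four base rows)."""
    path = Path(path)
    try:
        with open(path) as handle:
            parsed = motifs.parse(handle, "jaspar")
            records = list(parsed)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse JASPAR PFM ({exc})") from exc
    if not records:
        raise FormatError(f"{path}: no matrices found")
    pwms = []
    for m in records:
        counts = np.array([list(m.counts[b]) for b in BASES], dtype=float).T
        pwms.append(
            pwm_from_counts(
                matrix_id=m.matrix_id or m.name,
                tf_name=m.name or m.matrix_id,
                counts=counts,
                pseudocount=pseudocount,
            )
        )
    return pwms


def write_jaspar_pfm(
    pwms_counts: Sequence[tuple[str, str, np.ndarray]], path: str | Path
) -> None:
    """Write count matrices in JASPAR text format (``A [ ... ]`` rows)."""
    with open(path, "w") as out:
        for matrix_id, tf_name, counts in pwms_counts:
            counts = np.asarray(counts)
            out.write(f">{matrix_id} {tf_name}\n")
            for bi, base in enumerate(BASES):
                row = " ".join(f"{int(c):6d}" for c in counts[:, bi])
                out.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

DEG_COLUMNS = ("gene", "log2FoldChange", "padj")


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression results TSV.

    Requires columns ``gene``, ``log2FoldChange``, ``padj``.  Rows with
    missing ``padj`` are retained with NaN; downstream significance filters
    never call them significant (mirroring the independent-filtering
    semantics of standard DE tools).
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    missing = set(DEG_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    table = table.loc[:, list(DEG_COLUMNS)].copy()
    table["gene"] = table["gene"].astype(str)
    table["log2FoldChange"] = pd.to_numeric(table["log2FoldChange"])
    table["padj"] = pd.to_numeric(table["padj"], errors="coerce")
    return table


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
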