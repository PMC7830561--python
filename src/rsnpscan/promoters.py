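"""Strand-aware TSS and promoter geometry.

Internal convention: genomic intervals are 0-based half-open; the TSS-relative
offset of a promoter base is a signed integer where 0 is the TSS base itself,
downstream positions run 0 .. down-1 and upstream positions -1 .. -up, always
measured in transcription orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ParameterError, RsnpScanError
from .io_formats import GeneModel, GenomeSequences, SnpRecord

__all__ = [
    "PromoterRegion",
    "TssRelativePosition",
    "derive_tss",
    "promoter_window",
    "promoter_regions",
    "extract_promoter_sequence",
    "assign_snps_to_promoters",
    "snp_offset",
    "offset_to_genomic_pos",
    "position_histogram",
    "gc_content",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterRegion:
    """A promoter window anchored at a gene's TSS.

    ``abs_start``/``abs_end`` are the 0-based half-open genomic interval; when
    the window would extend past a chromosome boundary it is clipped and
    ``clipped`` is set rather than silently shortened.
    """

    gene_id: str
    chromosome: str
    strand: str
    tss: int  # 1-based TSS coordinate the window is anchored to
    up: int
    down: int
    abs_start: int
    abs_end: int
    clipped: bool = False

    def __len__(self) -> int:
        return self.abs_end - self.abs_start


@dataclass(frozen=True)
class TssRelativePosition:
    """A SNP assigned to a promoter, with its signed TSS-relative offset."""

    snp_id: str
    gene_id: str
    offset: int


def derive_tss(gene: GeneModel) -> int:
    """1-based TSS coordinate: gene start on '+', gene end on '-'."""
    return gene.start if gene.strand == "+" else gene.end


def promoter_window(
    tss: int,
    strand: str,
    chromosome: str = "",
    gene_id: str = "",
    up: int = 500,
    down: int = 100,
    chrom_length: int | None = None,
) -> PromoterRegion:
    """Build the promoter window around a TSS.

    On '+' the window covers genomic ``[tss-1-up, tss-1+down)`` (0-based
    half-open); on '-' it covers ``[tss-down, tss+up)``.  Both span
    ``up + down`` bases and contain the TSS base at offset 0.
    """
    if up < 0 or down < 0:
        raise ParameterError("promoter window: up and down must be >= 0")
    if strand not in "+-":
        raise ParameterError(f"promoter window: invalid strand {strand!r}")
    tss0 = tss - 1
    if strand == "+":
        start, end = tss0 - up, tss0 + down
    else:
        start, end = tss0 - down + 1, tss0 + up + 1
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_length is not None and end > chrom_length:
        end, clipped = chrom_length, True
    return PromoterRegion(
        gene_id=gene_id,
        chromosome=chromosome,
        strand=strand,
        tss=tss,
        up=up,
        down=down,
        abs_start=start,
        abs_end=end,
        clipped=clipped,
    )


def promoter_regions(
    genes: Iterable[GeneModel],
    genome: GenomeSequences | None = None,
    up: int = 500,
    down: int = 100,
) -> list[PromoterRegion]:
    """Promoter windows for a gene set, clipping against the genome if given."""
    regions = []
    for gene in genes:
        chrom_len = len(genome[gene.chromosome]) if genome is not None else None
        regions.append(
            promoter_window(
                tss=derive_tss(gene),
                strand=gene.strand,
                chromosome=gene.chromosome,
                gene_id=gene.gene_id,
                up=up,
                down=down,
                chrom_length=chrom_len,
            )
        )
    return regions


def extract_promoter_sequence(genome: GenomeSequences, region: PromoterRegion) -> str:
    """Promoter sequence in transcription orientation (5'→3').

    Minus-strand regions are reverse-complemented so that index 0 of the
    returned string is the most upstream base of the window.
    """
    if region.chromosome not in genome:
        raise RsnpScanError(f"chromosome {region.chromosome!r} not in genome")
    seq = genome[region.chromosome][region.abs_start : region.abs_end]
    return seq if region.strand == "+" else reverse_complement(seq)


def snp_offset(region: PromoterRegion, pos: int) -> int | None:
    """Signed TSS-relative offset of a 1-based genomic position, or None if
    the position falls outside the region."""
    p0 = pos - 1
    if not region.abs_start <= p0 < region.abs_end:
        return None
    tss0 = region.tss - 1
    return p0 - tss0 if region.strand == "+" else tss0 - p0


def offset_to_genomic_pos(region: PromoterRegion, offset: int) -> int:
    """Inverse of :func:`snp_offset`: 1-based genomic position of an offset."""
    tss0 = region.tss - 1
    p0 = tss0 + offset if region.strand == "+" else tss0 - offset
    return p0 + 1


def assign_snps_to_promoters(
    snps: Sequence[SnpRecord], regions: Sequence[PromoterRegion]
) -> list[TssRelativePosition]:
    """Assign each SNP to every promoter containing it.

    A SNP inside two overlapping promoters yields two records.  Offsets are
    signed and strand-aware (see module docstring).
    """
    by_chrom: dict[str, list[PromoterRegion]] = {}
    for region in regions:
        by_chrom.setdefault(region.chromosome, []).append(region)

    assignments: list[TssRelativePosition] = []
    for chrom, chrom_regions in by_chrom.items():
        chrom_regions.sort(key=lambda r: r.abs_start)
        starts = np.array([r.abs_start for r in chrom_regions])
        ends = np.array([r.abs_end for r in chrom_regions])
        max_len = int((ends - starts).max()) if len(chrom_regions) else 0
        for snp in snps:
            if snp.chromosome != chrom:
                continue
            p0 = snp.pos - 1
            # regions are sorted by start; any region containing p0 starts in
            # (p0 - max_len, p0], so only a bounded slice needs checking
            lo = int(np.searchsorted(starts, p0 - max_len, side="right"))
            hi = int(np.searchsorted(starts, p0, side="right"))
            for region in chrom_regions[lo:hi]:
                offset = snp_offset(region, snp.pos)
                if offset is not None:
                    assignments.append(
                        TssRelativePosition(
                            snp_id=snp.id, gene_id=region.gene_id, offset=offset
                        )
                    )
    return assignments


def position_histogram(
    positions: Iterable[TssRelativePosition],
    bin_width: int = 50,
    up: int = 500,
    down: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of TSS-relative offsets over half-open bins covering [-up, down).

    Returns ``(bin_edges, counts)``; counts sum to the number of input
    records that fall inside the range.
    """
    if bin_width < 1:
        raise ParameterError("bin_width must be >= 1")
    edges = np.arange(-up, down + bin_width, bin_width)
    offsets = np.array([p.offset for p in positions], dtype=float)
    if offsets.size == 0:
        return edges, np.zeros(len(edges) - 1, dtype=int)
    counts, _ = np.histogram(offsets, bins=edges)
    return edges, counts.astype(int)


def gc_content(sequence: str) -> float:
    """(G+C) fraction of a sequence, with N bases excluded from the denominator."""
    if not sequence:
        raise ParameterError("gc_content: empty sequence")
    n = sequence.count("N")
    denom = len(sequence) - n
    if denom == 0:
        raise ParameterError("gc_content: sequence is all N")
    return (sequence.count("G") + sequence.count("C")) / denom
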