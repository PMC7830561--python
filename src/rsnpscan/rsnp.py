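"""Allele-swap rSNP consequence engine.

For each promoter SNP, two copies of its ±k bp flanking sequence are built —
one carrying the reference allele at the center, one the alternate — both are
scanned against the PWM library, predictions that miss the MSS threshold or
do not overlap the SNP base are discarded, and every surviving SNP-TFBS pair
is classified as NoChange, ScoreChange, LossOfTFBS or GainOfTFBS.  A SNP is
an rSNP iff at least one pair is a Loss or a Gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataIntegrityError
from .io_formats import PWM, GenomeSequences, SnpRecord
from .motif_scan import ScoredSite, scan_sequence
from .promoters import TssRelativePosition

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 25
DEFAULT_THRESHOLD = 0.85
#: |delta MSS| at or below this is numerically "no change"
SCORE_EPS = 1e-9

__all__ = [
    "Consequence",
    "AlleleFlankPair",
    "ConsequenceRecord",
    "extract_flanks",
    "overlap_filter",
    "classify_pair",
    "classify_snps",
    "call_rsnps",
    "annotate_rsnp_positions",
]


class Consequence(str, Enum):
    NO_CHANGE = "NoChange"
    SCORE_CHANGE = "ScoreChange"
    LOSS_OF_TFBS = "LossOfTFBS"
    GAIN_OF_TFBS = "GainOfTFBS"


@dataclass(frozen=True)
class AlleleFlankPair:
    """Reference and alternate flank sequences, differing only at the center."""

    snp_id: str
    ref_seq: str
    alt_seq: str
    center: int  # 0-based index of the SNP base in both sequences

    def __post_init__(self) -> None:
        assert len(self.ref_seq) == len(self.alt_seq)
        assert self.ref_seq[: self.center] == self.alt_seq[: self.center]
        assert self.ref_seq[self.center + 1 :] == self.alt_seq[self.center + 1 :]


@dataclass(frozen=True)
class ConsequenceRecord:
    """One classified SNP-TFBS pair.

    ``site_start`` is the 0-based offset of the site within the flank;
    ``mss_ref``/``mss_alt`` are None when no threshold-passing site exists on
    that allele.
    """

    snp_id: str
    matrix_id: str
    tf_name: str
    site_start: int
    strand: str
    mss_ref: float | None
    mss_alt: float | None
    consequence: Consequence
    gene_id: str | None = None


def extract_flanks(
    genome: GenomeSequences, snp: SnpRecord, k: int = DEFAULT_FLANK
) -> AlleleFlankPair | None:
    """Build the (2k+1) bp ref/alt flank pair centered on a SNP.

    Returns None (with a log message) for SNPs within k bases of a
    chromosome edge; raises if the genome base disagrees with the REF allele.
    """
    if snp.chromosome not in genome:
        raise DataIntegrityError(f"SNP {snp.id}: chromosome {snp.chromosome!r} not in genome")
    chrom = genome[snp.chromosome]
    p0 = snp.pos - 1
    if p0 - k < 0 or p0 + k >= len(chrom):
        logger.warning("SNP %s: within %d bp of chromosome edge; skipped", snp.id, k)
        return None
    if chrom[p0] != snp.ref:
        raise DataIntegrityError(
            f"SNP {snp.id}: genome base {chrom[p0]} != REF {snp.ref} "
            f"at {snp.chromosome}:{snp.pos}"
        )
    window = chrom[p0 - k : p0 + k + 1]
    alt_seq = window[:k] + snp.alt + window[k + 1 :]
    return AlleleFlankPair(snp_id=snp.id, ref_seq=window, alt_seq=alt_seq, center=k)


def overlap_filter(sites: Iterable[ScoredSite], center: int = DEFAULT_FLANK) -> list[ScoredSite]:
    """Keep sites whose interval [start, start+L) covers the SNP base."""
    return [s for s in sites if s.start <= center < s.start + s.length]


def classify_pair(
    ref_sites: Sequence[ScoredSite],
    alt_sites: Sequence[ScoredSite],
    snp_id: str,
    threshold: float = DEFAULT_THRESHOLD,
    eps: float = SCORE_EPS,
) -> list[ConsequenceRecord]:
    """Classify SNP-TFBS pairs from threshold- and overlap-filtered site lists.

    Sites are matched across alleles by (matrix_id, site_start, strand).  A
    site found on both alleles is NoChange when |delta MSS| <= eps, else
    ScoreChange; ref-only sites are LossOfTFBS; alt-only sites GainOfTFBS.
    A site that shifts position under the allele swap therefore counts as a
    Loss plus a Gain, not a ScoreChange.
    """
    ref_by_key = {(s.matrix_id, s.start, s.strand): s for s in ref_sites}
    alt_by_key = {(s.matrix_id, s.start, s.strand): s for s in alt_sites}
    records: list[ConsequenceRecord] = []
    for key in sorted(ref_by_key.keys() | alt_by_key.keys()):
        r, a = ref_by_key.get(key), alt_by_key.get(key)
        site = r or a
        if r is not None and a is not None:
            kind = Consequence.NO_CHANGE if abs(r.mss - a.mss) <= eps else Consequence.SCORE_CHANGE
        elif r is not None:
            kind = Consequence.LOSS_OF_TFBS
        else:
            kind = Consequence.GAIN_OF_TFBS
        records.append(
            ConsequenceRecord(
                snp_id=snp_id,
                matrix_id=site.matrix_id,
                tf_name=site.tf_name,
                site_start=site.start,
                strand=site.strand,
                mss_ref=r.mss if r is not None else None,
                mss_alt=a.mss if a is not None else None,
                consequence=kind,
            )
        )
    return records


def classify_snps(
    genome: GenomeSequences,
    snps: Iterable[SnpRecord],
    pwms: Sequence[PWM],
    threshold: float = DEFAULT_THRESHOLD,
    k: int = DEFAULT_FLANK,
    strands: str = "both",
) -> list[ConsequenceRecord]:
    """Full consequence prediction for a SNP set against a PWM library."""
    records: list[ConsequenceRecord] = []
    for snp in snps:
        pair = extract_flanks(genome, snp, k=k)
        if pair is None:
            continue
        for pwm in pwms:
            ref_sites = overlap_filter(
                scan_sequence(pwm, pair.ref_seq, threshold=threshold, strands=strands),
                center=pair.center,
            )
            alt_sites = overlap_filter(
                scan_sequence(pwm, pair.alt_seq, threshold=threshold, strands=strands),
                center=pair.center,
            )
            if ref_sites or alt_sites:
                records.extend(
                    classify_pair(ref_sites, alt_sites, snp.id, threshold=threshold)
                )
    return records


def call_rsnps(consequences: Iterable[ConsequenceRecord]) -> set[str]:
    """SNP ids with >= 1 GainOfTFBS or LossOfTFBS record (the rSNP definition)."""
    return {
        rec.snp_id
        for rec in consequences
        if rec.consequence in (Consequence.LOSS_OF_TFBS, Consequence.GAIN_OF_TFBS)
    }


def annotate_rsnp_positions(
    rsnps: set[str], tss_assignments: Iterable[TssRelativePosition]
) -> pd.DataFrame:
    """TSS-relative positions of called rSNPs (one row per rSNP x host gene)."""
    rows = [
        {"snp_id": a.snp_id, "gene_id": a.gene_id, "offset": a.offset}
        for a in tss_assignments
        if a.snp_id in rsnps
    ]
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "offset"])
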