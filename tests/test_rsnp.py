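import numpy as np
import pytest

from rsnpscan.errors import DataIntegrityError
from rsnpscan.io_formats import SnpRecord
from rsnpscan.motif_scan import ScoredSite
from rsnpscan.promoters import TssRelativePosition
from rsnpscan import rsnp as rs


def snp(pos, ref, alt, chrom="c1", sid="s1"):
    return SnpRecord(id=sid, chromosome=chrom, pos=pos, ref=ref, alt=alt, maf=0.1)


def site(matrix_id="M1", start=22, length=6, strand="+", mss=0.9):
    return ScoredSite(
        matrix_id=matrix_id, tf_name="tf", start=start, length=length, strand=strand, mss=mss
    )


# ---------------------------------------------------------------------- flanks

def test_extract_flanks_minimal_case():
    genome = {"c1": "ACG"}
    pair = rs.extract_flanks(genome, snp(2, "C", "G"), k=1)
    assert (pair.ref_seq, pair.alt_seq) == ("ACG", "AGG")


def test_extract_flanks_substitutes_only_center():
    genome = {"c1": "AAAAACGTCAAAAA"}
    pair = rs.extract_flanks(genome, snp(7, "G", "T"), k=3)
    assert pair.ref_seq == "AACGTCA"
    assert pair.ref_seq[3] == "G" and pair.alt_seq[3] == "T"
    diff = [i for i, (a, b) in enumerate(zip(pair.ref_seq, pair.alt_seq)) if a != b]
    assert diff == [3]


def test_extract_flanks_hamming_one_on_fixture(small_dataset):
    ds = small_dataset
    for s in ds.snps[:30]:
        pair = rs.extract_flanks(ds.genome, s, k=25)
        assert pair is not None
        assert len(pair.ref_seq) == 51
        diff = sum(a != b for a, b in zip(pair.ref_seq, pair.alt_seq))
        assert diff == 1 and pair.ref_seq[25] == s.ref and pair.alt_seq[25] == s.alt


def test_extract_flanks_near_edge_skipped(caplog):
    genome = {"c1": "ACGTACGTAC"}
    assert rs.extract_flanks(genome, snp(2, "C", "T"), k=5) is None


def test_extract_flanks_ref_mismatch_raises():
    genome = {"c1": "AAAAAAAAAA"}
    with pytest.raises(DataIntegrityError, match="s1"):
        rs.extract_flanks(genome, snp(5, "C", "T"), k=2)


# -------------------------------------------------------------- overlap filter

@pytest.mark.parametrize("start,kept", [(20, True), (25, True), (26, False), (19, False)])
def test_overlap_filter_boundaries(start, kept):
    sites = rs.overlap_filter([site(start=start, length=6)], center=25)
    assert bool(sites) is kept


# -------------------------------------------------------------- classification

def test_classify_ref_only_is_loss():
    (rec,) = rs.classify_pair([site(mss=0.91)], [], "s1")
    assert rec.consequence is rs.Consequence.LOSS_OF_TFBS
    assert rec.mss_ref == 0.91 and rec.mss_alt is None


def test_classify_alt_only_is_gain():
    # e.g. a DOF-family site created by a C->T substitution
    (rec,) = rs.classify_pair([], [site(mss=0.88)], "s1")
    assert rec.consequence is rs.Consequence.GAIN_OF_TFBS
    assert rec.mss_ref is None and rec.mss_alt == 0.88


def test_classify_matched_score_change_and_no_change():
    (rec,) = rs.classify_pair([site(mss=0.86)], [site(mss=0.93)], "s1")
    assert rec.consequence is rs.Consequence.SCORE_CHANGE
    (rec,) = rs.classify_pair([site(mss=0.90)], [site(mss=0.90)], "s1")
    assert rec.consequence is rs.Consequence.NO_CHANGE


def test_site_shifting_position_counts_as_loss_plus_gain():
    recs = rs.classify_pair([site(start=22)], [site(start=23)], "s1")
    kinds = sorted(r.consequence.value for r in recs)
    assert kinds == ["GainOfTFBS", "LossOfTFBS"]


# ------------------------------------------------------------------ rSNP calls

def test_score_change_only_is_not_rsnp():
    recs = rs.classify_pair([site(mss=0.86)], [site(mss=0.93)], "s1")
    assert rs.call_rsnps(recs) == set()


def test_one_gain_among_no_changes_is_rsnp():
    recs = rs.classify_pair([], [site(mss=0.9)], "s1")
    recs += rs.classify_pair([site(mss=0.9)], [site(mss=0.9)], "s1")
    assert rs.call_rsnps(recs) == {"s1"}


def test_planted_rsnp_set_recovered_exactly(small_dataset):
    ds = small_dataset
    records = rs.classify_snps(ds.genome, ds.snps, ds.pwms)
    called = rs.call_rsnps(records)
    planted = set(ds.truth.loc[ds.truth["planted"] != "neutral", "snp_id"])
    assert called == planted


def test_no_site_on_either_allele_yields_no_records():
    genome = {"c1": "A" * 101}
    pwm = small_pwm()
    records = rs.classify_snps(genome, [snp(51, "A", "T")], [pwm])
    assert records == []


def small_pwm():
    from rsnpscan.io_formats import pwm_from_counts

    counts = np.array([[0, 90, 5, 5]] * 6)  # CCCCCC-preferring motif
    return pwm_from_counts("M1", "tf", counts)


# ------------------------------------------------------------ allele symmetry

def swap_alleles(genome, s):
    """Mutate the genome to carry the alternate allele and swap the SNP."""
    chrom = bytearray(genome[s.chromosome], "ascii")
    chrom[s.pos - 1] = ord(s.alt)
    g2 = dict(genome)
    g2[s.chromosome] = chrom.decode()
    swapped = SnpRecord(
        id=s.id, chromosome=s.chromosome, pos=s.pos, ref=s.alt, alt=s.ref, maf=s.maf
    )
    return g2, swapped


def test_allele_swap_flips_loss_and_gain(small_dataset):
    ds = small_dataset
    flip = {
        rs.Consequence.LOSS_OF_TFBS: rs.Consequence.GAIN_OF_TFBS,
        rs.Consequence.GAIN_OF_TFBS: rs.Consequence.LOSS_OF_TFBS,
        rs.Consequence.NO_CHANGE: rs.Consequence.NO_CHANGE,
        rs.Consequence.SCORE_CHANGE: rs.Consequence.SCORE_CHANGE,
    }
    for s in ds.snps[:40]:
        fwd = rs.classify_snps(ds.genome, [s], ds.pwms)
        g2, swapped = swap_alleles(ds.genome, s)
        rev = rs.classify_snps(g2, [swapped], ds.pwms)
        key = lambda r: (r.matrix_id, r.site_start, r.strand)
        fwd_map = {key(r): r.consequence for r in fwd}
        rev_map = {key(r): r.consequence for r in rev}
        assert rev_map == {k: flip[v] for k, v in fwd_map.items()}


# ------------------------------------------------------------------ positions

def test_annotate_rsnp_positions_offsets():
    assignments = [
        TssRelativePosition(snp_id="a", gene_id="g1", offset=90),
        TssRelativePosition(snp_id="b", gene_id="g1", offset=-247),
        TssRelativePosition(snp_id="c", gene_id="g2", offset=-5),
    ]
    table = rs.annotate_rsnp_positions({"a", "b"}, assignments)
    assert table["offset"].tolist() == [90, -247]


def test_annotate_empty_rsnp_set():
    assignments = [TssRelativePosition(snp_id="a", gene_id="g1", offset=1)]
    table = rs.annotate_rsnp_positions(set(), assignments)
    assert table.empty and list(table.columns) == ["snp_id", "gene_id", "offset"]
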