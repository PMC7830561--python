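import numpy as np
import pytest

from rsnpscan.errors import ParameterError
from rsnpscan.io_formats import GeneModel, SnpRecord
from rsnpscan import promoters as pm


def gene(strand="+", start=1000, end=2000, gid="g1", chrom="c1"):
    return GeneModel(gene_id=gid, chromosome=chrom, strand=strand, start=start, end=end)


# ------------------------------------------------------------------------ TSS

def test_derive_tss_by_strand():
    assert pm.derive_tss(gene("+")) == 1000
    assert pm.derive_tss(gene("-")) == 2000


def test_mirrored_genes_have_mirrored_tss():
    # same interval, opposite strands: TSSs sit at opposite ends
    g_plus, g_minus = gene("+"), gene("-")
    assert pm.derive_tss(g_plus) == g_plus.start
    assert pm.derive_tss(g_minus) == g_minus.end
    assert pm.derive_tss(g_plus) + pm.derive_tss(g_minus) == g_plus.start + g_plus.end


# -------------------------------------------------------------------- windows

def test_promoter_window_plus_strand_defaults():
    r = pm.promoter_window(tss=1000, strand="+")
    assert (r.abs_start, r.abs_end) == (499, 1099)
    assert len(r) == 600 and not r.clipped


def test_promoter_window_minus_strand_defaults():
    r = pm.promoter_window(tss=1000, strand="-")
    assert (r.abs_start, r.abs_end) == (900, 1500)
    assert len(r) == 600 and not r.clipped


def test_promoter_window_clipped_and_flagged():
    r = pm.promoter_window(tss=100, strand="+")
    assert r.abs_start == 0 and r.clipped


def test_promoter_window_rejects_negative_extent():
    with pytest.raises(ParameterError):
        pm.promoter_window(tss=100, strand="+", up=-1)


def test_unclipped_length_constant_across_strands():
    for strand in "+-":
        for tss in (1000, 5000, 12345):
            assert len(pm.promoter_window(tss=tss, strand=strand)) == 600


# ------------------------------------------------------------------ sequences

def test_extract_plus_strand_is_verbatim_slice():
    genome = {"c1": "AACGTTTTGGCCA" * 100}
    r = pm.promoter_window(tss=700, strand="+", chromosome="c1", up=10, down=5)
    seq = pm.extract_promoter_sequence(genome, r)
    assert seq == genome["c1"][r.abs_start : r.abs_end]


def test_extract_minus_strand_reverse_complements():
    genome = {"c1": "A" * 50 + "ACGTTGCA" + "A" * 50}
    r = pm.promoter_window(tss=54, strand="-", chromosome="c1", up=4, down=4)
    seq = pm.extract_promoter_sequence(genome, r)
    fwd = genome["c1"][r.abs_start : r.abs_end]
    assert seq == pm.reverse_complement(fwd)
    assert pm.reverse_complement(pm.reverse_complement(seq)) == seq


def test_extraction_recovers_planted_sequence(small_dataset):
    ds = small_dataset
    regions = pm.promoter_regions(
        ds.genes, ds.genome, up=ds.config.promoter_up, down=ds.config.promoter_down
    )
    for r in regions[:5]:
        seq = pm.extract_promoter_sequence(ds.genome, r)
        assert len(seq) == len(r)
        raw = ds.genome[r.chromosome][r.abs_start : r.abs_end]
        assert seq == (raw if r.strand == "+" else pm.reverse_complement(raw))


# ----------------------------------------------------------------- assignment

def snp(pos, chrom="c1", sid="s1"):
    return SnpRecord(id=sid, chromosome=chrom, pos=pos, ref="A", alt="C", maf=0.1)


def test_offset_minus_152_upstream():
    # a SNP 152 bp upstream of a plus-strand TSS has offset -152
    r = pm.promoter_window(tss=10000, strand="+", chromosome="c1", gene_id="g1")
    (a,) = pm.assign_snps_to_promoters([snp(10000 - 152)], [r])
    assert a.offset == -152


def test_offset_zero_at_tss_base():
    for strand in "+-":
        r = pm.promoter_window(tss=10000, strand=strand, chromosome="c1", gene_id="g1")
        (a,) = pm.assign_snps_to_promoters([snp(10000)], [r])
        assert a.offset == 0


def test_snp_in_two_overlapping_promoters_yields_two_records():
    r1 = pm.promoter_window(tss=10000, strand="+", chromosome="c1", gene_id="g1")
    r2 = pm.promoter_window(tss=10050, strand="-", chromosome="c1", gene_id="g2")
    got = pm.assign_snps_to_promoters([snp(9990)], [r1, r2])
    assert {a.gene_id for a in got} == {"g1", "g2"}


def test_assignment_matches_bruteforce_oracle():
    rng = np.random.default_rng(42)
    regions = [
        pm.promoter_window(
            tss=int(rng.integers(600, 50_000)),
            strand=rng.choice(["+", "-"]),
            chromosome=f"c{rng.integers(1, 3)}",
            gene_id=f"g{i}",
        )
        for i in range(40)
    ]
    snps = [
        snp(int(rng.integers(1, 50_000)), chrom=f"c{rng.integers(1, 3)}", sid=f"s{i}")
        for i in range(300)
    ]
    got = {(a.snp_id, a.gene_id, a.offset) for a in pm.assign_snps_to_promoters(snps, regions)}
    expected = set()
    for s in snps:  # O(n*m) containment check
        for r in regions:
            if r.chromosome == s.chromosome and r.abs_start <= s.pos - 1 < r.abs_end:
                off = (s.pos - r.tss) if r.strand == "+" else (r.tss - s.pos)
                expected.add((s.id, r.gene_id, off))
    assert got == expected


def test_offset_roundtrip_recovers_vcf_position(small_dataset):
    ds = small_dataset
    regions = pm.promoter_regions(
        ds.genes, ds.genome, up=ds.config.promoter_up, down=ds.config.promoter_down
    )
    by_gene = {r.gene_id: r for r in regions}
    assignments = pm.assign_snps_to_promoters(ds.snps, regions)
    assert assignments  # the fixture plants SNPs in promoters
    pos_of = {s.id: s.pos for s in ds.snps}
    for a in assignments:
        region = by_gene[a.gene_id]
        assert pm.offset_to_genomic_pos(region, a.offset) == pos_of[a.snp_id]
        assert -region.up <= a.offset < region.down


# ------------------------------------------------------------------ histogram

def test_histogram_empty_input_all_zero():
    edges, counts = pm.position_histogram([], bin_width=50)
    assert counts.sum() == 0 and len(counts) == len(edges) - 1


def test_histogram_bins_are_half_open():
    rec = pm.TssRelativePosition(snp_id="s", gene_id="g", offset=-1)
    edges, counts = pm.position_histogram([rec], bin_width=50, up=500, down=100)
    bin_index = int(np.searchsorted(edges, -1, side="right")) - 1
    assert edges[bin_index] == -50 and counts[bin_index] == 1
    assert counts.sum() == 1


def test_histogram_uniform_offsets_flat():
    rng = np.random.default_rng(7)
    n, up, down, width = 6000, 500, 100, 50
    offsets = rng.integers(-up, down, size=n)
    recs = [
        pm.TssRelativePosition(snp_id=f"s{i}", gene_id="g", offset=int(o))
        for i, o in enumerate(offsets)
    ]
    edges, counts = pm.position_histogram(recs, bin_width=width, up=up, down=down)
    assert counts.sum() == n
    p = width / (up + down)
    sd = np.sqrt(n * p * (1 - p))
    assert np.all(np.abs(counts - n * p) < 4 * sd)


# ----------------------------------------------------------------- GC content

@pytest.mark.parametrize(
    "seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("GCAT", 0.5), ("GCN", 1.0)]
)
def test_gc_content(seq, expected):
    assert pm.gc_content(seq) == expected


def test_gc_content_all_n_rejected():
    with pytest.raises(ParameterError):
        pm.gc_content("NNN")
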