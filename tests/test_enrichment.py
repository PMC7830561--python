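import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from conftest import random_pwm
from rsnpscan.errors import RsnpScanError
from rsnpscan import enrichment as en
from rsnpscan.motif_scan import consensus_word, scan_sequence
from rsnpscan.promoters import gc_content


def hypergeom_tail_exact(fg_hits, fg_total, bg_hits, bg_total):
    """P(X >= fg_hits) for X ~ Hypergeom(N, K, fg_total), exact rationals."""
    N = fg_total + bg_total
    K = fg_hits + bg_hits
    total = Fraction(math.comb(N, fg_total))
    tail = Fraction(0)
    for x in range(fg_hits, min(K, fg_total) + 1):
        if K - x <= bg_total:
            tail += Fraction(math.comb(K, x) * math.comb(N - K, fg_total - x))
    return float(tail / total)


# ------------------------------------------------------------------ background

def make_seqs(rng, n, gc, length=120, prefix="g"):
    out = {}
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    for i in range(n):
        out[f"{prefix}{i}"] = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return out


def test_background_matches_foreground_gc_histogram():
    rng = np.random.default_rng(0)
    seqs = {}
    for gc in (0.3, 0.5, 0.7):
        seqs.update(make_seqs(rng, 40, gc, prefix=f"gc{int(gc*100)}_"))
    fg = [g for g in seqs if g.startswith("gc30")][:10] + [
        g for g in seqs if g.startswith("gc70")
    ][:10]
    candidates = [g for g in seqs if g not in set(fg)]
    bg = en.select_background(fg, candidates, seqs, bin_width=0.05, seed=1)
    assert len(bg) == len(fg)
    assert not set(bg) & set(fg)

    def hist(genes):
        bins = [int(gc_content(seqs[g]) / 0.05) for g in genes]
        return pd.Series(bins).value_counts().sort_index()

    # ample pool: per-bin counts match exactly
    pd.testing.assert_series_equal(hist(fg), hist(bg), check_names=False)


def test_background_is_deterministic_given_seed():
    rng = np.random.default_rng(1)
    seqs = make_seqs(rng, 80, 0.4)
    fg = sorted(seqs)[:20]
    candidates = sorted(set(seqs) - set(fg))
    a = en.select_background(fg, candidates, seqs, seed=7)
    b = en.select_background(fg, candidates, seqs, seed=7)
    assert a == b


def test_background_deficit_raises():
    rng = np.random.default_rng(2)
    seqs = make_seqs(rng, 10, 0.4)
    fg = sorted(seqs)[:8]
    candidates = sorted(set(seqs) - set(fg))
    with pytest.raises(RsnpScanError, match="deficit"):
        en.select_background(fg, candidates, seqs, ratio=2, seed=0)


def test_background_borrows_from_adjacent_bins_with_warning():
    rng = np.random.default_rng(3)
    seqs = {**make_seqs(rng, 12, 0.25, prefix="lo"), **make_seqs(rng, 30, 0.6, prefix="hi")}
    fg = [g for g in seqs if g.startswith("lo")][:10]
    candidates = sorted(set(seqs) - set(fg))
    with pytest.warns(UserWarning, match="borrowing"):
        bg = en.select_background(fg, candidates, seqs, seed=0)
    assert len(bg) == len(fg)


# -------------------------------------------------------------------- presence

def test_presence_detects_planted_consensus_and_skips_mismatched():
    rng = np.random.default_rng(4)
    pwm = random_pwm(rng, 8)
    cons = consensus_word(pwm)
    seqs = {"hit": "ATAT" * 10 + cons + "ATAT" * 10, "miss": "A" * 100}
    matrix = en.tfbs_presence(seqs, [pwm], threshold=0.85)
    assert matrix.loc["hit", pwm.matrix_id] == 1
    assert matrix.loc["miss", pwm.matrix_id] == 0


def test_presence_column_sums_match_direct_scans():
    rng = np.random.default_rng(5)
    pwms = [random_pwm(rng, int(rng.integers(6, 10))) for _ in range(4)]
    seqs = make_seqs(rng, 25, 0.5, length=200)
    matrix = en.tfbs_presence(seqs, pwms, threshold=0.8)
    for pwm in pwms:
        direct = sum(
            bool(scan_sequence(pwm, s, threshold=0.8)) for s in seqs.values()
        )
        assert matrix[pwm.matrix_id].sum() == direct


# ------------------------------------------------------------------ enrichment

def presence_frame(rows, n_genes, prefix):
    data = {f"M{j}": rows[j] for j in range(len(rows))}
    return pd.DataFrame(data, index=[f"{prefix}{i}" for i in range(n_genes)])


def test_equal_proportions_not_enriched():
    fg = pd.DataFrame({"M0": [1] * 30 + [0] * 20})
    bg = pd.DataFrame({"M0": [1] * 30 + [0] * 20})
    (res,) = en.enrich(fg, bg)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p_value >= 0.5 and not res.enriched


def test_fisher_matches_hypergeometric_enumeration():
    fg = pd.DataFrame({"M0": [1] * 40 + [0] * 10})
    bg = pd.DataFrame({"M0": [1] * 10 + [0] * 40})
    (res,) = en.enrich(fg, bg)
    assert res.p_value == pytest.approx(hypergeom_tail_exact(40, 50, 10, 50), rel=1e-10)


def test_fisher_oracle_agreement_small_tables():
    for fg_total in (3, 7, 12):
        for bg_total in (4, 9, 15):
            for fg_hits in range(fg_total + 1):
                for bg_hits in range(bg_total + 1):
                    fg = pd.DataFrame({"M0": [1] * fg_hits + [0] * (fg_total - fg_hits)})
                    bg = pd.DataFrame({"M0": [1] * bg_hits + [0] * (bg_total - bg_hits)})
                    (res,) = en.enrich(fg, bg)
                    oracle = hypergeom_tail_exact(fg_hits, fg_total, bg_hits, bg_total)
                    assert res.p_value == pytest.approx(oracle, rel=1e-9, abs=1e-12)


def test_planted_motif_is_unique_enriched_hit():
    rng = np.random.default_rng(6)
    n_matrices, n_genes = 20, 50
    cols = {}
    for j in range(n_matrices):
        base = rng.uniform(0.05, 0.3)
        cols[f"M{j}"] = (base, base)
    cols["M0"] = (0.8, 0.1)  # planted: 80% fg presence vs 10% bg
    fg = pd.DataFrame(
        {m: rng.binomial(1, p_fg, size=n_genes) for m, (p_fg, _) in cols.items()}
    )
    bg = pd.DataFrame(
        {m: rng.binomial(1, p_bg, size=n_genes) for m, (_, p_bg) in cols.items()}
    )
    results = en.enrich(fg, bg, alpha=0.01)
    enriched = [r.matrix_id for r in results if r.enriched]
    assert enriched == ["M0"]


def test_null_familywise_error_rate_controlled():
    rng = np.random.default_rng(7)
    n_rep, n_matrices, n_genes = 100, 20, 50
    false_hits = 0
    for _ in range(n_rep):
        probs = rng.uniform(0.1, 0.5, size=n_matrices)
        fg = pd.DataFrame(
            {f"M{j}": rng.binomial(1, probs[j], n_genes) for j in range(n_matrices)}
        )
        bg = pd.DataFrame(
            {f"M{j}": rng.binomial(1, probs[j], n_genes) for j in range(n_matrices)}
        )
        results = en.enrich(fg, bg, alpha=0.01)
        false_hits += any(r.enriched for r in results)
    assert false_hits / n_rep <= 0.05


def test_enriched_set_monotone_in_alpha():
    rng = np.random.default_rng(8)
    fg = pd.DataFrame({f"M{j}": rng.binomial(1, 0.6, 40) for j in range(5)})
    bg = pd.DataFrame({f"M{j}": rng.binomial(1, 0.2, 40) for j in range(5)})
    strict = {r.matrix_id for r in en.enrich(fg, bg, alpha=0.001) if r.enriched}
    loose = {r.matrix_id for r in en.enrich(fg, bg, alpha=0.05) if r.enriched}
    assert strict <= loose


def test_empty_table_p_one():
    fg = pd.DataFrame({"M0": []})
    bg = pd.DataFrame({"M0": []})
    (res,) = en.enrich(fg, bg)
    assert res.p_value == 1.0 and not res.enriched
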