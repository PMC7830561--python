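"""TFBS over-representation in DEG promoters versus GC-matched backgrounds.

The foreground is the promoter set of a tissue's differentially expressed
genes; the background is drawn from non-DEG promoters so that its GC-content
histogram matches the foreground's (binned matching, foreground genes
excluded).  Per matrix, a one-sided Fisher exact test compares the fraction
of foreground vs background promoters containing at least one site at or
above the MSS threshold; p-values are Bonferroni-corrected over the matrices
actually tested and a TF is called enriched below an adjusted 0.01.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .errors import ParameterError, RsnpScanError
from .io_formats import PWM
from .motif_scan import scan_sequence
from .promoters import gc_content

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "select_background",
    "tfbs_presence",
    "enrich",
    "enrichment_table",
]


@dataclass(frozen=True)
class EnrichmentResult:
    matrix_id: str
    tf_name: str
    fg_hits: int
    fg_total: int
    bg_hits: int
    bg_total: int
    odds_ratio: float
    p_value: float
    p_bonferroni: float
    enriched: bool


def select_background(
    fg_genes: Sequence[str],
    candidate_genes: Sequence[str],
    promoter_seqs: Mapping[str, str],
    ratio: int = 1,
    bin_width: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Sample a GC-matched background gene set.

    For every foreground promoter, ``ratio`` background promoters are drawn
    without replacement from candidates in the same GC bin; a bin whose pool
    is exhausted borrows from the nearest neighbouring bins with a warning.
    Foreground genes are excluded from the candidates.  Raises when the
    total candidate pool cannot supply the request.
    """
    if ratio < 1:
        raise ParameterError("background ratio must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fg_set = set(fg_genes)
    candidates = [g for g in candidate_genes if g not in fg_set]
    need = ratio * len(fg_genes)
    if len(candidates) < need:
        raise RsnpScanError(
            f"background pool too small: need {need}, have {len(candidates)} "
            f"(deficit {need - len(candidates)})"
        )

    def gc_bin(gene: str) -> int:
        return int(gc_content(promoter_seqs[gene]) / bin_width)

    pool: dict[int, list[str]] = {}
    for gene in sorted(candidates):
        pool.setdefault(gc_bin(gene), []).append(gene)
    for genes in pool.values():
        rng.shuffle(genes)

    demand: dict[int, int] = {}
    for gene in fg_genes:
        b = gc_bin(gene)
        demand[b] = demand.get(b, 0) + ratio

    background: list[str] = []
    for b in sorted(demand):
        want = demand[b]
        take = pool.get(b, [])
        chosen, pool[b] = take[:want], take[want:]
        short = want - len(chosen)
        if short > 0:
            warnings.warn(
                f"GC bin {b * bin_width:.2f}-{(b + 1) * bin_width:.2f}: "
                f"short by {short}; borrowing from adjacent bins"
            )
            for dist in range(1, max(pool.keys() | {b}) + len(pool) + 2):
                for nb in (b - dist, b + dist):
                    while short > 0 and pool.get(nb):
                        chosen.append(pool[nb].pop(0))
                        short -= 1
                if short == 0:
                    break
        background.extend(chosen)
    return background


def tfbs_presence(
    promoter_seqs: Mapping[str, str],
    pwms: Sequence[PWM],
    threshold: float = 0.85,
    strands: str = "both",
) -> pd.DataFrame:
    """Binary gene x matrix presence matrix.

    Cell (g, m) is 1 iff promoter g contains >= 1 site for matrix m with
    MSS >= threshold on either strand.
    """
    genes = list(promoter_seqs)
    data = np.zeros((len(genes), len(pwms)), dtype=int)
    for j, pwm in enumerate(pwms):
        for i, gene in enumerate(genes):
            sites = scan_sequence(
                pwm, promoter_seqs[gene], threshold=threshold, strands=strands
            )
            if sites:
                data[i, j] = 1
    return pd.DataFrame(data, index=genes, columns=[p.matrix_id for p in pwms])


def enrich(
    fg: pd.DataFrame,
    bg: pd.DataFrame,
    pwms: Sequence[PWM] | None = None,
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """One-sided Fisher over-representation test per matrix, Bonferroni over
    the matrices tested."""
    if list(fg.columns) != list(bg.columns):
        raise ParameterError("foreground and background matrices differ in columns")
    names = {p.matrix_id: p.tf_name for p in pwms} if pwms else {}
    n_tests = fg.shape[1]
    results = []
    for matrix_id in fg.columns:
        fg_hits = int(fg[matrix_id].sum())
        bg_hits = int(bg[matrix_id].sum())
        fg_total, bg_total = len(fg), len(bg)
        if fg_total == 0 or bg_total == 0:
            odds, p = float("nan"), 1.0
        else:
            table = [
                [fg_hits, fg_total - fg_hits],
                [bg_hits, bg_total - bg_hits],
            ]
            odds, p = fisher_exact(table, alternative="greater")
        p_bonf = min(1.0, p * n_tests)
        results.append(
            EnrichmentResult(
                matrix_id=matrix_id,
                tf_name=names.get(matrix_id, matrix_id),
                fg_hits=fg_hits,
                fg_total=fg_total,
                bg_hits=bg_hits,
                bg_total=bg_total,
                odds_ratio=float(odds),
                p_value=float(p),
                p_bonferroni=float(p_bonf),
                enriched=bool(p_bonf < alpha),
            )
        )
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
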