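"""MATCH-style PWM scanning.

A DNA word is scored against a PWM with the matrix similarity score (MSS):
the per-position frequencies of the observed bases, weighted by the column
information vector I(i) = sum_b f(i,b) * ln(4 f(i,b)), min-max normalized so
that the per-position argmax word (the consensus) scores exactly 1 and the
per-position argmin word scores exactly 0.  Sliding-window scanning on both
strands reports every site at or above an MSS threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .io_formats import BASES, PWM

__all__ = [
    "ScoredSite",
    "information_vector",
    "mss",
    "scan_sequence",
    "consensus_word",
    "anticonsensus_word",
]

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i


def encode(sequence: str) -> np.ndarray:
    """Map a sequence to integer codes A,C,G,T -> 0..3; anything else -> 4."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoredSite:
    """One predicted binding site within a scanned sequence.

    ``start`` is the 0-based offset of the site's leftmost base in the
    scanned (forward) sequence regardless of strand; minus-strand sites were
    scored on the reverse complement of that window.
    """

    matrix_id: str
    tf_name: str
    start: int
    length: int
    strand: str
    mss: float


def information_vector(pwm: PWM) -> np.ndarray:
    """Per-column conservation weights I(i) = sum_b f(i,b) ln(4 f(i,b)).

    Zero for a uniform column, approaching ln 4 for a fully conserved one.
    """
    f = pwm.freqs
    return np.sum(f * np.log(4.0 * f), axis=1)


def _score_bounds(pwm: PWM) -> tuple[np.ndarray, float, float]:
    """I-weighted frequency matrix and the (min, max) achievable raw scores."""
    info = information_vector(pwm)
    weighted = info[:, None] * pwm.freqs
    return weighted, float(weighted.min(axis=1).sum()), float(weighted.max(axis=1).sum())


def mss(pwm: PWM, word: str) -> float:
    """Matrix similarity score of ``word`` against ``pwm``, in [0, 1]."""
    codes = encode(word)
    if len(codes) != len(pwm):
        raise ParameterError(
            f"{pwm.matrix_id}: word length {len(word)} != matrix length {len(pwm)}"
        )
    if np.any(codes > 3):
        raise ParameterError(f"word {word!r} contains non-ACGT characters")
    weighted, lo, hi = _score_bounds(pwm)
    if hi - lo <= 0.0:
        raise ParameterError(
            f"{pwm.matrix_id}: all columns uniform; matrix is unscorable"
        )
    current = float(weighted[np.arange(len(pwm)), codes].sum())
    return (current - lo) / (hi - lo)


def consensus_word(pwm: PWM) -> str:
    """Per-position argmax word; ties broken in A<C<G<T order."""
    return "".join(BASES[i] for i in np.argmax(pwm.freqs, axis=1))


def anticonsensus_word(pwm: PWM) -> str:
    """Per-position argmin word; ties broken in A<C<G<T order."""
    return "".join(BASES[i] for i in np.argmin(pwm.freqs, axis=1))


def scan_sequence(
    pwm: PWM,
    sequence: str,
    threshold: float = 0.85,
    strands: str = "both",
) -> list[ScoredSite]:
    """Slide ``pwm`` over ``sequence`` and report sites with MSS >= threshold.

    Minus-strand candidates are scored by applying the matrix to the reverse
    complement of each window; windows containing N are skipped on both
    strands.  ``strands`` is '+', '-' or 'both'.
    """
    if strands not in ("+", "-", "both"):
        raise ParameterError(f"invalid strand policy {strands!r}")
    L = len(pwm)
    codes = encode(sequence.upper())
    n_windows = len(codes) - L + 1
    if n_windows <= 0:
        return []

    weighted, lo, hi = _score_bounds(pwm)
    if hi - lo <= 0.0:
        raise ParameterError(
            f"{pwm.matrix_id}: all columns uniform; matrix is unscorable"
        )

    # windows free of N: valid[j] iff codes[j:j+L] are all < 4
    is_base = (codes < 4).astype(np.int32)
    cums = np.concatenate(([0], np.cumsum(is_base)))
    valid = (cums[L:] - cums[:-L]) == L

    safe = np.where(codes > 3, 0, codes)  # placeholder for N; masked by `valid`
    fwd = np.zeros(n_windows)
    rev = np.zeros(n_windows)
    want_fwd = strands in ("+", "both")
    want_rev = strands in ("-", "both")
    for i in range(L):
        col = safe[i : i + n_windows]
        if want_fwd:
            fwd += weighted[i, col]
        if want_rev:
            # PWM applied to revcomp(window): position i reads the complement
            # of window base L-1-i
            rev += weighted[L - 1 - i, 3 - col]

    sites: list[ScoredSite] = []
    span = hi - lo
    for strand, raw, wanted in (("+", fwd, want_fwd), ("-", rev, want_rev)):
        if not wanted:
            continue
        scores = (raw - lo) / span
        for j in np.nonzero(valid & (scores >= threshold))[0]:
            sites.append(
                ScoredSite(
                    matrix_id=pwm.matrix_id,
                    tf_name=pwm.tf_name,
                    start=int(j),
                    length=L,
                    strand=strand,
                    mss=float(scores[j]),
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites
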