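"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import math

import numpy as np
import pytest

from rsnpscan.io_formats import PWM, pwm_from_counts
from rsnpscan.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=101,
        n_chromosomes=2,
        chromosome_length=80_000,
        n_genes=30,
        n_gain=8,
        n_loss=8,
        n_neutral=16,
        n_samples_per_class=(30, 30),
        n_up=5,
        n_down=5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_all(small_config)


def random_pwm(
    rng: np.random.Generator,
    length: int,
    sharp: bool = True,
    dom_range: tuple[int, int] = (60, 96),
) -> PWM:
    """A random PWM; sharp ones have a dominant base per column."""
    if sharp:
        counts = np.zeros((length, 4), dtype=float)
        for i in range(length):
            dom = int(rng.integers(4))
            dom_count = int(rng.integers(*dom_range))
            rest = 100 - dom_count
            others = rng.multinomial(rest, [1 / 3] * 3)
            counts[i] = np.insert(others.astype(float), dom, float(dom_count))
    else:
        counts = rng.uniform(1, 100, size=(length, 4))
    return pwm_from_counts(f"RND{rng.integers(1e6):06d}", "rnd", counts)


def mss_oracle(pwm: PWM, word: str) -> float:
    """Independent MSS recomputation in plain Python (no numpy reuse)."""
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(pwm)
    freqs = [[float(pwm.freqs[i, b]) for b in range(4)] for i in range(L)]
    info = [sum(f * math.log(4 * f) for f in row) for row in freqs]
    current = sum(info[i] * freqs[i][base_index[word[i]]] for i in range(L))
    lo = sum(info[i] * min(freqs[i]) for i in range(L))
    hi = sum(info[i] * max(freqs[i]) for i in range(L))
    return (current - lo) / (hi - lo)
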