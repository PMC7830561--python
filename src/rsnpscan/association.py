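"""Boruta all-relevant feature selection over rSNP genotypes.

Each iteration appends one shuffled "shadow" copy of every undecided feature
to the genotype matrix, fits a random-forest classifier on cultivar labels,
and converts per-tree Gini importances into a z-score (mean / sd across
trees).  A feature scores a hit when its z-score exceeds the best shadow's.
Accumulated hits are tested against a fair coin (two-sided binomial test):
significantly more hits confirms the feature, significantly fewer rejects
it; decided features leave the matrix and the loop continues until all are
decided or the iteration cap leaves the rest tentative.

The consensus rule intersects the confirmed sets of independently seeded
repeat runs: an rSNP is *important* only if confirmed in every run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier

from .errors import ParameterError

logger = logging.getLogger(__name__)

#: depth cap for the forests (standard Boruta practice; limits variance of
#: Gini importances and keeps iteration cost bounded)
DEFAULT_MAX_DEPTH = 7

__all__ = [
    "Decision",
    "BorutaRunResult",
    "load_genotypes",
    "impute_mode",
    "shadow_augment",
    "rf_importance",
    "boruta_run",
    "consensus_important",
]


def binomial_two_sided(hits: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for Binomial(n, 0.5) hit counts.

    The null is symmetric, so the two-sided p-value is the probability of a
    deviation from n/2 at least as large as observed: 2*CDF(min(k, n-k)),
    capped at 1.  Agrees with scipy.stats.binomtest at p=0.5.
    """
    hits = np.asarray(hits)
    m = np.minimum(hits, n - hits)
    return np.minimum(1.0, 2.0 * binom.cdf(m, n, 0.5))


class Decision(str, Enum):
    CONFIRMED = "Confirmed"
    REJECTED = "Rejected"
    TENTATIVE = "Tentative"


@dataclass
class BorutaRunResult:
    """Outcome of one Boruta run."""

    decisions: dict[str, Decision]
    importance_history: dict[str, list[float]]  # z-score per iteration while undecided
    iterations: int
    seed: int

    @property
    def confirmed(self) -> set[str]:
        return {f for f, d in self.decisions.items() if d is Decision.CONFIRMED}


def load_genotypes(
    genotype_path: str, labels_path: str
) -> tuple[pd.DataFrame, pd.Series]:
    """Read a samples x rSNPs genotype TSV ({0,1,2} alt-allele counts) and a
    two-column (sample, label) TSV, aligned on sample id."""
    M = pd.read_csv(genotype_path, sep="\t", index_col=0)
    lab = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0]
    missing = set(M.index) - set(lab.index)
    if missing:
        raise ParameterError(f"samples without labels: {sorted(missing)[:5]} ...")
    return M, lab.loc[M.index]


def impute_mode(M: pd.DataFrame) -> pd.DataFrame:
    """Fill missing genotypes with the per-feature mode."""
    if not M.isna().any().any():
        return M
    M = M.copy()
    for col in M.columns[M.isna().any()]:
        mode = M[col].mode(dropna=True)
        M[col] = M[col].fillna(mode.iloc[0] if len(mode) else 0)
    return M


def shadow_augment(
    M: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Append one independently row-permuted shadow column per feature.

    Returns the extended matrix (width doubled) and the number of original
    features; shadow j is a permutation of feature j, so it preserves the
    marginal distribution while destroying any association with the labels.
    """
    n, p = M.shape
    shadows = np.empty_like(M)
    for j in range(p):
        shadows[:, j] = M[rng.permutation(n), j]
    return np.hstack([M, shadows]), p


def rf_importance(
    extended: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    n_trees: int = 500,
    max_depth: int | None = DEFAULT_MAX_DEPTH,
) -> np.ndarray:
    """Variable-importance z-score per column of ``extended``.

    Fits a random forest and returns, per column, mean per-tree Gini
    importance divided by its standard deviation across trees.  Columns
    whose importance never varies (sd = 0) get z = 0 with a warning.
    """
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ParameterError("labels contain a single class")
    counts = np.bincount(np.searchsorted(classes, labels))
    if counts.min() < 2:
        raise ParameterError("need >= 2 samples in each class")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        max_features="sqrt",
        class_weight="balanced_subsample",
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    forest.fit(extended, labels)
    per_tree = np.array([t.feature_importances_ for t in forest.estimators_])
    mean = per_tree.mean(axis=0)
    sd = per_tree.std(axis=0, ddof=1)
    z = np.zeros_like(mean)
    nonzero = sd > 0
    z[nonzero] = mean[nonzero] / sd[nonzero]
    if not nonzero.all():
        warnings.warn(f"{(~nonzero).sum()} columns with zero importance variance; z set to 0")
    return z


def boruta_run(
    M: pd.DataFrame,
    L: pd.Series | np.ndarray,
    max_iter: int = 100,
    n_trees: int = 500,
    hit_alpha: float = 0.05,
    seed: int = 0,
    max_depth: int | None = DEFAULT_MAX_DEPTH,
) -> BorutaRunResult:
    """One full Boruta run over a genotype matrix.

    Shadows are re-shuffled every iteration.  After each iteration every
    undecided feature's accumulated hit count (times its z-score beat the
    best shadow) is tested against Binomial(iterations, 0.5); a two-sided
    p-value below ``hit_alpha`` decides the feature in the direction of the
    deviation.  Decided features are removed before the next iteration.
    """
    if max_iter < 1:
        raise ParameterError("max_iter must be >= 1")
    features = list(M.columns)
    X_full = impute_mode(M).to_numpy(dtype=float)
    y = np.asarray(L)
    rng = np.random.default_rng(seed)

    undecided = list(range(len(features)))
    hits = np.zeros(len(features), dtype=int)
    rounds = np.zeros(len(features), dtype=int)
    decisions: dict[str, Decision] = {}
    history: dict[str, list[float]] = {f: [] for f in features}

    it = 0
    while undecided and it < max_iter:
        it += 1
        X = X_full[:, undecided]
        extended, p = shadow_augment(X, rng)
        with warnings.catch_warnings():
            # zero-variance shadow columns are routine inside the loop
            warnings.simplefilter("ignore", UserWarning)
            z = rf_importance(extended, y, rng, n_trees=n_trees, max_depth=max_depth)
        shadow_max = z[p:].max()
        for local_j, j in enumerate(undecided):
            history[features[j]].append(float(z[local_j]))
            rounds[j] += 1
            if z[local_j] > shadow_max:
                hits[j] += 1
        idx = np.array(undecided)
        pvals = binomial_two_sided(hits[idx], it)
        still = []
        for j, pval in zip(undecided, pvals):
            if pval < hit_alpha:
                decisions[features[j]] = (
                    Decision.CONFIRMED if hits[j] > rounds[j] / 2 else Decision.REJECTED
                )
            else:
                still.append(j)
        undecided = still

    for j in undecided:
        decisions[features[j]] = Decision.TENTATIVE
    return BorutaRunResult(
        decisions=decisions, importance_history=history, iterations=it, seed=seed
    )


def consensus_important(
    M: pd.DataFrame,
    L: pd.Series | np.ndarray,
    n_runs: int = 20,
    base_seed: int = 0,
    max_iter: int = 100,
    n_trees: int = 500,
    hit_alpha: float = 0.05,
    max_depth: int | None = DEFAULT_MAX_DEPTH,
) -> set[str]:
    """Intersection of confirmed sets over ``n_runs`` independently seeded runs.

    Tentative never counts as confirmed.  The loop short-circuits once the
    running intersection is empty — by intersection monotonicity the result
    is identical to running all repeats.
    """
    if n_runs < 1:
        raise ParameterError("n_runs must be >= 1")
    seeds = run_seeds(base_seed, n_runs)
    important: set[str] | None = None
    for seed in seeds:
        result = boruta_run(
            M,
            L,
            max_iter=max_iter,
            n_trees=n_trees,
            hit_alpha=hit_alpha,
            seed=seed,
            max_depth=max_depth,
        )
        important = result.confirmed if important is None else important & result.confirmed
        if not important:
            return set()
    return important or set()


def run_seeds(base_seed: int, n_runs: int) -> list[int]:
    """Deterministic per-run seeds derived from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_runs)]
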