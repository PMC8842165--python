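"""Frequent-flier detection by the rank-product method.

Promiscuous preys ("frequent fliers") show strong signal in screens of
unrelated control baits.  Each control screen's CPMs are ranked
descending (highest CPM = rank 1, ties get average ranks) and each
prey's rank product is the geometric mean of its per-screen ranks.  A
small rank product means consistently strong signal across screens.

Significance comes from a permutation null: each screen's rank column is
independently permuted, randomized rank products are recomputed, and a
prey's p-value is the fraction of iterations in which the randomized
rank product at its position is <= its observed rank product.  P-values
are then Benjamini-Hochberg adjusted and preys at adjusted p <= alpha
are flagged as fliers.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, rankdata


@dataclass
class ControlScreenMatrix:
    """CPM matrix over control-bait screens (ORF x screen)."""

    orf_ids: list[str]
    cpm: np.ndarray
    screen_labels: list[str]

    def __post_init__(self) -> None:
        self.cpm = np.asarray(self.cpm, dtype=float)
        if self.cpm.ndim != 2:
            raise ValueError("cpm must be 2-D (ORF x screen)")
        if self.cpm.shape != (len(self.orf_ids), len(self.screen_labels)):
            raise ValueError("cpm shape inconsistent with labels")
        if self.cpm.shape[1] < 2:
            raise ValueError("at least 2 control screens are required")
        if (self.cpm < 0).any():
            raise ValueError("CPM values must be non-negative")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ControlScreenMatrix":
        return cls(
            orf_ids=list(df.index),
            cpm=df.to_numpy(dtype=float),
            screen_labels=list(df.columns),
        )

    @classmethod
    def from_tsv(cls, path) -> "ControlScreenMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col="orf_id"))


def _rank_matrix(cpm: np.ndarray) -> np.ndarray:
    """Descending ranks per screen column; rank 1 = highest CPM.

    Ties receive the average of the tied rank positions, so rank sums
    are conserved.  Zero-CPM preys are ranked (tied last), not imputed.
    """
    return np.column_stack(
        [rankdata(-cpm[:, j], method="average") for j in range(cpm.shape[1])]
    )


def compute_rank_products(m: ControlScreenMatrix) -> np.ndarray:
    """Geometric mean of each prey's per-screen CPM ranks."""
    ranks = _rank_matrix(m.cpm)
    return np.exp(np.mean(np.log(ranks), axis=1))


def permutation_pvalues(
    m: ControlScreenMatrix,
    n_iter: int = 100_000,
    seed: int | np.random.Generator = 0,
    strict: bool = False,
    add_one: bool = False,
    chunk: int = 500,
) -> np.ndarray:
    """Permutation p-values for the observed rank products.

    In each iteration every screen's rank column is independently
    permuted and randomized rank products recomputed; ``p[i]`` is the
    fraction of iterations in which the randomized rank product at
    position i is <= the observed rank product of prey i (``strict=True``
    switches to <).  ``add_one`` applies the (b+1)/(n+1) correction;
    it is off by default, matching division by the plain iteration
    count.  Reproducible given ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n, s = m.cpm.shape
    if n_iter < 20 / 0.05:
        warnings.warn(
            f"n_iter={n_iter} is small; p-values below 1/{n_iter} are not resolvable",
            stacklevel=2,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ranks = _rank_matrix(m.cpm)
    log_ranks = np.log(ranks)
    obs = log_ranks.sum(axis=1)
    hits = np.zeros(n, dtype=np.int64)
    done = 0
    # exact-tie tolerance: permuted columns sum the same multiset of
    # floats in a different order, so allow last-ulp slack
    eps = 1e-9
    while done < n_iter:
        b = min(chunk, n_iter - done)
        null_sum = np.zeros((b, n))
        for j in range(s):
            col = np.broadcast_to(log_ranks[:, j], (b, n))
            null_sum += rng.permuted(col, axis=1)
        if strict:
            hits += (null_sum < obs[None, :] - eps).sum(axis=0)
        else:
            hits += (null_sum <= obs[None, :] + eps).sum(axis=0)
        done += b
    if add_one:
        return (hits + 1) / (n_iter + 1)
    return hits / n_iter


def exact_permutation_pvalues(
    m: ControlScreenMatrix, strict: bool = False
) -> np.ndarray:
    """Exhaustive-enumeration p-values over all joint rank permutations.

    Enumerates all (n!)^s joint column permutations; feasible only for
    tiny instances (<= ~5 preys x 3 screens).  Independent oracle for
    :func:`permutation_pvalues`.
    """
    n, s = m.cpm.shape
    if math.factorial(n) ** s > 2_000_000:
        raise ValueError("instance too large for exhaustive enumeration")
    ranks = _rank_matrix(m.cpm)
    log_ranks = np.log(ranks)
    obs = log_ranks.sum(axis=1)
    perms = list(itertools.permutations(range(n)))
    hits = np.zeros(n, dtype=np.int64)
    total = 0
    eps = 1e-9
    for combo in itertools.product(perms, repeat=s):
        null = np.zeros(n)
        for j, perm in enumerate(combo):
            null += log_ranks[list(perm), j]
        if strict:
            hits += null < obs - eps
        else:
            hits += null <= obs + eps
        total += 1
    return hits / total


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return false_discovery_control(p, method="bh")


@dataclass
class RankProductResult:
    """Per-prey rank-product statistics over the control screens."""

    table: pd.DataFrame  # orf_id, rank_product, p_value, p_adjusted, is_flier
    n_iter: int
    seed: int | None
    alpha: float

    def fliers(self) -> list[str]:
        return list(self.table.loc[self.table["is_flier"], "orf_id"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def flag_frequent_fliers(
    m: ControlScreenMatrix,
    n_iter: int = 100_000,
    alpha: float = 0.05,
    seed: int = 0,
    strict: bool = False,
    add_one: bool = False,
) -> RankProductResult:
    """Full rank-product pipeline: ranks, permutation p, BH, flier flags."""
    rp = compute_rank_products(m)
    p = permutation_pvalues(m, n_iter=n_iter, seed=seed, strict=strict, add_one=add_one)
    p_adj = bh_adjust(p)
    # alpha = 0 disables flagging outright (a Monte-Carlo p can be exactly 0)
    flags = (p_adj <= alpha) & (alpha > 0)
    table = pd.DataFrame(
        {
            "orf_id": m.orf_ids,
            "rank_product": rp,
            "p_value": p,
            "p_adjusted": p_adj,
            "is_flier": flags,
        }
    )
    return RankProductResult(table=table, n_iter=n_iter, seed=seed, alpha=alpha)
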