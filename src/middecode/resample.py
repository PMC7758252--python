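"""Bootstrap pseudo-epoch resampling.

Raw preprocessed epochs are grouped into per-condition sampling pools.  For
each classifier iteration, ``n_means`` (default 21) pseudo-epochs are formed
per condition by averaging ``n_draw`` (default 10) epochs drawn from the pool
(without replacement within a draw, with replacement across draws), then
z-scoring each pseudo-epoch per channel.  Averaging raises the effective SNR
by roughly sqrt(n_draw) before classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .errors import ValidationError
from .preprocess import zscore_epochs
from .synth import EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingPool",
    "PseudoEpochSet",
    "build_pool",
    "draw_mean_epochs",
    "bootstrap_iterator",
]


@dataclass
class SamplingPool:
    """Per-condition epoch pools for one participant.

    ``conditions`` maps a class label to a list of member arrays, each of
    shape (n_epochs, n_channels, n_times).  Plain conditions have one member;
    pooled superclasses (see :func:`middecode.decode.pool_conditions`) have
    one member per merged condition so bootstrap draws can stay balanced.
    """

    participant_id: str
    conditions: dict[str, list[np.ndarray]]
    times_ms: np.ndarray

    def __post_init__(self) -> None:
        sizes = {k: sum(m.shape[0] for m in v) for k, v in self.conditions.items()}
        if len(set(sizes.values())) > 1:
            raise ValidationError(f"unequal pool sizes across conditions: {sizes}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.conditions)

    @property
    def pool_size(self) -> int:
        return sum(m.shape[0] for m in next(iter(self.conditions.values())))

    @property
    def total_epochs(self) -> int:
        return self.pool_size * len(self.conditions)


@dataclass
class PseudoEpochSet:
    """One iteration's mean bootstrapped, z-scored epochs per condition."""

    data: dict[str, np.ndarray]  # label -> (n_means, n_channels, n_times)
    n_draw: int
    iteration_index: int
    seed: object = None
    times_ms: Optional[np.ndarray] = None

    @property
    def n_means(self) -> int:
        return next(iter(self.data.values())).shape[0]


def build_pool(epochs: EpochSet) -> SamplingPool:
    """Partition a participant's epochs by condition label."""
    if epochs.n_epochs == 0:
        raise ValidationError("cannot build a sampling pool from an empty EpochSet")
    labels = np.unique(epochs.labels)
    conditions = {str(lab): [epochs.data[epochs.labels == lab]] for lab in labels}
    return SamplingPool(
        participant_id=epochs.participant_id,
        conditions=conditions,
        times_ms=epochs.times_ms,
    )


def _member_indices(rng: np.random.Generator, pool_n: int, per: int,
                    n_means: int) -> np.ndarray:
    """Draw indices for ``n_means`` pseudo-epochs, ``per`` epochs each.

    When the pool is large enough, the ``n_means`` draws partition a random
    permutation of the pool, so no raw epoch is reused within one iteration:
    pseudo-epochs are then statistically independent given the noise model,
    and held-out pseudo-epochs share no raw data with the training ones.
    Reusing raw epochs across pseudo-epochs would leak the pool's realized
    noise mean into the leave-one-out test and inflate accuracy above chance
    even for pure noise, so the fallback (independent without-replacement
    draws per pseudo-epoch) is used only when the pool is too small.
    """
    if per * n_means <= pool_n:
        perm = rng.permutation(pool_n)
        return perm[: per * n_means].reshape(n_means, per)
    logger.info(
        "pool size %d < n_draw x n_means = %d: pseudo-epochs will share raw "
        "epochs (leave-one-out optimism possible)", pool_n, per * n_means,
    )
    return np.stack(
        [rng.choice(pool_n, size=per, replace=False) for _ in range(n_means)]
    )


def draw_mean_epochs(pool: SamplingPool, n_draw: int = 10, n_means: int = 21,
                     seed=0, iteration_index: int = 0,
                     standardize: bool = True,
                     zscore_axis: str = "channels") -> PseudoEpochSet:
    """Draw-and-average one full set of pseudo-epochs (then z-score each).

    Draws are without replacement within a pseudo-epoch and, whenever the
    pool permits, disjoint across the ``n_means`` pseudo-epochs of one
    iteration; balanced across member sub-pools for pooled superclasses.
    """
    if n_draw < 1 or n_means < 1:
        raise ValidationError("n_draw and n_means must be >= 1")
    if n_draw > pool.pool_size:
        raise ValidationError(
            f"n_draw={n_draw} exceeds pool size {pool.pool_size}"
        )
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for label, members in pool.conditions.items():
        k = len(members)
        if n_draw % k != 0:
            raise ValidationError(
                f"n_draw={n_draw} not divisible across {k} pooled member conditions"
            )
        per = n_draw // k
        sums = np.zeros((n_means,) + members[0].shape[1:])
        for m in members:
            if per > m.shape[0]:
                raise ValidationError(
                    f"n_draw/member={per} exceeds member pool size {m.shape[0]}"
                )
            idx = _member_indices(rng, m.shape[0], per, n_means)
            sums += m[idx].sum(axis=1)
        means = sums / n_draw
        out[label] = zscore_epochs(means, zscore_axis) if standardize else means
    return PseudoEpochSet(
        data=out, n_draw=n_draw, iteration_index=iteration_index, seed=seed,
        times_ms=pool.times_ms,
    )


def bootstrap_iterator(pool: SamplingPool, n_iterations: int, base_seed: int = 0,
                       n_draw: int = 10, n_means: int = 21,
                       zscore_axis: str = "channels"
                       ) -> Iterator[PseudoEpochSet]:
    """Reproducible stream of independent pseudo-epoch sets.

    Iteration ``i`` uses the counter-based child seed
    ``SeedSequence(base_seed, spawn_key=(i,))`` so any iteration can be
    regenerated independently (parallel-safe).
    """
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    for i in range(n_iterations):
        child = np.random.SeedSequence(entropy=base_seed, spawn_key=(i,))
        yield draw_mean_epochs(pool, n_draw=n_draw, n_means=n_means, seed=child,
                               iteration_index=i, zscore_axis=zscore_axis)
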