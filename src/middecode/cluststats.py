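"""Group-level significance of decoding timecourses.

Pointwise one-sample t-tests against the 50 % chance level are thresholded
at a cluster-forming alpha; temporally adjacent suprathreshold timepoints
form clusters whose mass is the sum of member t-values.  Significance is
assessed against a permutation null distribution of maximum cluster masses
obtained by flipping the sign of each participant's (accuracy - chance)
timecourse (a valid one-sample null under symmetric between-participant
variation).  A Bonferroni-corrected pointwise test is provided as the
conventional alternative.

The default cluster-forming test is one-sided (above chance), since
below-chance decoding is not interpretable here; a two-sided variant is
available via ``tail="two-sided"`` (clusters are then formed on |t| and
signed runs are kept separate).  Degenerate zero-variance timepoints yield
infinite t sentinels whose contribution to cluster mass is capped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "Cluster",
    "ClusterResult",
    "pointwise_tstats",
    "form_clusters",
    "permutation_null",
    "significant_clusters",
    "cluster_test",
    "bonferroni_pointwise",
]

T_CAP = 100.0  # cap for infinite-t sentinels when summing cluster mass


@dataclass
class Cluster:
    start: int  # first timepoint index (inclusive)
    end: int  # last timepoint index (inclusive)
    mass: float  # sum of member t-values (capped at +/- T_CAP each)
    p_value: Optional[float] = None
    significant: Optional[bool] = None


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    tstats: np.ndarray
    n_participants: int
    alpha_forming: float
    cluster_alpha: float
    tail: str
    n_permutations: int
    seed: Optional[int] = None
    null_distribution: Optional[np.ndarray] = None

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


def _validate_matrix(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2:
        raise ValidationError("accuracy matrix must be (participants, timepoints)")
    if mat.shape[0] < 2:
        raise ValidationError("need at least 2 participants")
    if np.nanmin(mat) < 0 or np.nanmax(mat) > 1:
        raise ValidationError("accuracies must lie in [0, 1]")
    return mat


def pointwise_tstats(mat: np.ndarray, chance: float = 0.5) -> np.ndarray:
    """One-sample t vs chance at each timepoint: (mean - chance) / (sd / sqrt(n)).

    Zero-variance timepoints yield +/-inf (0 if the mean equals chance).
    """
    mat = _validate_matrix(mat)
    n = mat.shape[0]
    mean = mat.mean(axis=0) - chance
    sd = mat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_sd = sd == 0
    t[zero_sd & (mean > 0)] = np.inf
    t[zero_sd & (mean < 0)] = -np.inf
    t[zero_sd & (mean == 0)] = 0.0
    return t


def _critical_t(n: int, alpha_forming: float, tail: str) -> float:
    df = n - 1
    if tail == "greater":
        return float(stats.t.ppf(1.0 - alpha_forming, df))
    if tail == "two-sided":
        return float(stats.t.ppf(1.0 - alpha_forming / 2.0, df))
    raise ValidationError(f"unknown tail {tail!r}")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def form_clusters(t: np.ndarray, n_participants: int,
                  alpha_forming: float = 0.05, tail: str = "greater"
                  ) -> list[Cluster]:
    """Cluster temporally adjacent suprathreshold timepoints; mass = sum of t."""
    t = np.asarray(t, dtype=float)
    crit = _critical_t(n_participants, alpha_forming, tail)
    capped = np.clip(t, -T_CAP, T_CAP)
    clusters: list[Cluster] = []
    if tail == "greater":
        for s, e in _runs(t > crit):
            clusters.append(Cluster(s, e, float(capped[s:e + 1].sum())))
    else:
        # two-sided: suprathreshold on |t|, but keep signed runs separate
        for sign in (+1, -1):
            for s, e in _runs(sign * t > crit):
                clusters.append(Cluster(s, e, float(capped[s:e + 1].sum())))
        clusters.sort(key=lambda c: c.start)
    return clusters


def _max_mass(t: np.ndarray, n: int, alpha_forming: float, tail: str) -> float:
    clusters = form_clusters(t, n, alpha_forming, tail)
    if not clusters:
        return 0.0
    return max(abs(c.mass) for c in clusters)


def _tstats_from_signs(dev: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-statistics for sign-flipped deviations, vectorized over permutations.

    ``dev``: (n, T) accuracy deviations from chance; ``signs``: (P, n).
    Whole-timecourse flips leave sum(dev^2) invariant, so only the mean needs
    recomputing per permutation.
    """
    n = dev.shape[0]
    sq = (dev**2).sum(axis=0)  # (T,)
    mean = signs @ dev / n  # (P, T)
    var = (sq[None, :] - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t[(var == 0) & (mean > 0)] = np.inf
    t[(var == 0) & (mean < 0)] = -np.inf
    t[(var == 0) & (mean == 0)] = 0.0
    return t


def permutation_null(mat: np.ndarray, n_permutations: int = 5000, seed: int = 0,
                     chance: float = 0.5, alpha_forming: float = 0.05,
                     tail: str = "greater", exhaustive: bool = False
                     ) -> np.ndarray:
    """Null distribution of maximum cluster mass under participant sign flips.

    Each permutation flips the sign of (accuracy - chance) for a random
    subset of participants (each participant's whole timecourse flips
    together), recomputes t and clusters, and records the largest absolute
    cluster mass (0 when no cluster forms).  With ``exhaustive=True`` all
    2^n sign patterns are enumerated instead (small n only).
    """
    mat = _validate_matrix(mat)
    dev = mat - chance
    n = mat.shape[0]
    if exhaustive:
        if n > 20:
            raise ValidationError("exhaustive enumeration limited to n <= 20")
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        if n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_permutations, n))
    null = np.empty(signs.shape[0])
    block = 1024
    for lo in range(0, signs.shape[0], block):
        t_block = _tstats_from_signs(dev, signs[lo:lo + block])
        for j, t in enumerate(t_block):
            null[lo + j] = _max_mass(t, n, alpha_forming, tail)
    return null


def significant_clusters(clusters: Sequence[Cluster], null: np.ndarray,
                         cluster_alpha: float = 0.05,
                         exhaustive: bool = False) -> list[Cluster]:
    """Attach permutation p-values; p = (1 + #{null >= mass}) / (1 + P).

    With an exhaustive null the plain proportion is used (the identity
    permutation is already included in the enumeration).
    """
    null = np.asarray(null, dtype=float)
    out = []
    for c in clusters:
        mass = abs(c.mass)
        if exhaustive:
            p = float(np.mean(null >= mass))
        else:
            p = float((1 + np.sum(null >= mass)) / (1 + null.size))
        out.append(Cluster(c.start, c.end, c.mass, p_value=p,
                           significant=p < cluster_alpha))
    return out


def cluster_test(mat: np.ndarray, chance: float = 0.5,
                 alpha_forming: float = 0.05, cluster_alpha: float = 0.05,
                 n_permutations: int = 5000, seed: int = 0,
                 tail: str = "greater", exhaustive: bool = False,
                 keep_null: bool = False) -> ClusterResult:
    """Full cluster-mass permutation test of decoding accuracy vs chance."""
    mat = _validate_matrix(mat)
    t = pointwise_tstats(mat, chance)
    clusters = form_clusters(t, mat.shape[0], alpha_forming, tail)
    null = permutation_null(mat, n_permutations=n_permutations, seed=seed,
                            chance=chance, alpha_forming=alpha_forming,
                            tail=tail, exhaustive=exhaustive)
    clusters = significant_clusters(clusters, null, cluster_alpha, exhaustive)
    return ClusterResult(
        clusters=clusters, tstats=t, n_participants=mat.shape[0],
        alpha_forming=alpha_forming, cluster_alpha=cluster_alpha, tail=tail,
        n_permutations=int(null.size), seed=seed,
        null_distribution=null if keep_null else None,
    )


def bonferroni_pointwise(mat: np.ndarray, alpha: float = 0.05,
                         chance: float = 0.5, tail: str = "greater"
                         ) -> np.ndarray:
    """Pointwise significance flags at the Bonferroni-corrected threshold."""
    mat = _validate_matrix(mat)
    t = pointwise_tstats(mat, chance)
    df = mat.shape[0] - 1
    if tail == "greater":
        p = stats.t.sf(t, df)
    elif tail == "two-sided":
        p = 2 * stats.t.sf(np.abs(t), df)
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    return p < alpha / mat.shape[1]
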