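"""Per-timepoint pairwise linear-SVM decoding of EEG pseudo-epochs.

For each bootstrap iteration and each timepoint, a linear soft-margin SVM is
trained on the 64-channel patterns of two classes of pseudo-epochs and
evaluated leave-one-out.  The default fold scheme holds out one pseudo-epoch
*per class* per fold (21 folds, 40 training epochs, 2 test items), keeping
training balanced; a plain leave-one-out scheme (41 train, 1 test) is
available via ``fold_scheme="leave-one-out"``.  Variants cover pooled
superclasses (direction pooled over cue, cue pooled over direction),
cross-trained decoding (train on one cue's direction pair, test on the
other's), and decoding after relabeling epochs (controls).

Class labels are sorted; a decision value of exactly zero predicts the class
with the lower sort order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from ._svm import svm_fit_batch
from .errors import ConfigurationError, ValidationError
from .resample import PseudoEpochSet, SamplingPool, bootstrap_iterator, build_pool
from .synth import EpochSet, MID_CONDITIONS

__all__ = [
    "DecodeConfig",
    "LinearModel",
    "DecodingTimecourse",
    "fit_linear_svm",
    "loo_accuracy_at_timepoint",
    "decode_timecourse",
    "pool_conditions",
    "cross_decode_timecourse",
    "relabel_and_decode",
]

logger = logging.getLogger(__name__)

_CHUNK = 4096  # batched-solver chunk; results are chunking-invariant


@dataclass
class DecodeConfig:
    n_iterations: int = 1000
    n_draw: int = 10
    n_means: int = 21
    C: float = 1.0
    fold_scheme: str = "leave-one-per-class"  # or "leave-one-out"
    base_seed: int = 0
    keep_iterations: bool = False
    zscore_axis: str = "channels"

    def __post_init__(self) -> None:
        if self.fold_scheme not in ("leave-one-per-class", "leave-one-out"):
            raise ConfigurationError(f"unknown fold scheme {self.fold_scheme!r}")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.zscore_axis not in ("channels", "time"):
            raise ConfigurationError(f"unknown zscore_axis {self.zscore_axis!r}")


@dataclass
class LinearModel:
    """Linear decision rule: sign(<w, x> + b) selects the class."""

    w: np.ndarray
    b: float
    C: float
    classes: tuple

    def decision_value(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        dec = self.decision_value(np.atleast_2d(X))
        n_ties = int(np.sum(dec == 0.0))
        if n_ties:
            logger.info("%d tied decision value(s); predicting lower-sorted class",
                        n_ties)
        return np.where(dec > 0, self.classes[1], self.classes[0])


@dataclass
class DecodingTimecourse:
    """Per-timepoint mean decoding accuracy for one binary comparison."""

    participant_id: str
    comparison: str
    times_ms: np.ndarray
    accuracy: np.ndarray  # (n_times,), mean over iterations, in [0, 1]
    n_iterations: int
    fold_scheme: str
    seed: int
    per_iteration: Optional[np.ndarray] = None  # (n_iterations, n_times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": self.participant_id,
                "comparison": self.comparison,
                "time_ms": self.times_ms,
                "accuracy": self.accuracy,
                "n_iterations": self.n_iterations,
                "seed": self.seed,
            }
        )


def fit_linear_svm(X: np.ndarray, y: Sequence, C: float = 1.0) -> LinearModel:
    """Fit one soft-margin linear SVM (libsvm solver via scikit-learn)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes.size}")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 training points")
    svc = SVC(kernel="linear", C=C, tol=1e-5)
    svc.fit(X, y)
    return LinearModel(
        w=svc.coef_[0].copy(), b=float(svc.intercept_[0]), C=C,
        classes=tuple(svc.classes_.tolist()),
    )


# ---------------------------------------------------------------------------
# batched LOO machinery


def _class_arrays(pseudo: PseudoEpochSet, pair: Sequence[str]
                  ) -> tuple[str, str, np.ndarray, np.ndarray]:
    a, b = sorted(pair)
    for lab in (a, b):
        if lab not in pseudo.data:
            raise ValidationError(f"condition {lab!r} missing from pseudo-epoch set")
    return a, b, pseudo.data[a], pseudo.data[b]


def _solve_chunked(X: np.ndarray, y: np.ndarray, C: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    Ws, bs = [], []
    for lo in range(0, X.shape[0], _CHUNK):
        W, b = svm_fit_batch(X[lo: lo + _CHUNK], y, C)
        Ws.append(W)
        bs.append(b)
    return np.concatenate(Ws), np.concatenate(bs)


def _loo_correct_counts(A: np.ndarray, B: np.ndarray, C: float, fold_scheme: str
                        ) -> np.ndarray:
    """Correct-prediction counts per timepoint, summed over folds.

    A, B: (m, d, T) pseudo-epochs of the lower- and higher-sorted class.
    Returns an integer array (T,); divide by the number of test items
    (2m for leave-one-per-class, 2m for leave-one-out as well — every
    pseudo-epoch is tested exactly once in both schemes).
    """
    m, d, T = A.shape
    idx = np.arange(m)
    if fold_scheme == "leave-one-per-class":
        y = np.concatenate([-np.ones(m - 1), np.ones(m - 1)])
        X = np.empty((m, T, 2 * (m - 1), d))
        for k in range(m):
            tr = np.delete(idx, k)
            Xk = np.concatenate([A[tr], B[tr]], axis=0)  # (2(m-1), d, T)
            X[k] = np.moveaxis(Xk, 2, 0)
        W, b = _solve_chunked(X.reshape(m * T, 2 * (m - 1), d), y, C)
        W = W.reshape(m, T, d)
        b = b.reshape(m, T)
        dec_a = np.einsum("ktd,kdt->kt", W, A) + b
        dec_b = np.einsum("ktd,kdt->kt", W, B) + b
        return (dec_a <= 0).sum(axis=0) + (dec_b > 0).sum(axis=0)
    # leave-one-out: 2m folds of 2m-1 training epochs, 1 test item each
    counts = np.zeros(T, dtype=int)
    for held, test_sign in ((A, -1), (B, +1)):
        other = B if test_sign < 0 else A
        y = np.concatenate(
            [-np.ones(m - 1) if test_sign < 0 else -np.ones(m),
             np.ones(m) if test_sign < 0 else np.ones(m - 1)]
        )
        X = np.empty((m, T, 2 * m - 1, d))
        for k in range(m):
            tr = np.delete(idx, k)
            if test_sign < 0:
                Xk = np.concatenate([A[tr], B], axis=0)
            else:
                Xk = np.concatenate([A, B[tr]], axis=0)
            X[k] = np.moveaxis(Xk, 2, 0)
        W, b = _solve_chunked(X.reshape(m * T, 2 * m - 1, d), y, C)
        W = W.reshape(m, T, d)
        b = b.reshape(m, T)
        dec = np.einsum("ktd,kdt->kt", W, held) + b
        counts += ((dec <= 0) if test_sign < 0 else (dec > 0)).sum(axis=0)
    return counts


def loo_accuracy_at_timepoint(pseudo: PseudoEpochSet, pair: Sequence[str],
                              t_index: int, C: float = 1.0,
                              fold_scheme: str = "leave-one-per-class") -> float:
    """Leave-one-out accuracy at a single timepoint (features: all channels)."""
    a, b, A, B = _class_arrays(pseudo, pair)
    T = A.shape[2]
    if not -T <= t_index < T:
        raise ValidationError(f"t_index {t_index} out of range for {T} timepoints")
    At = A[:, :, [t_index]]
    Bt = B[:, :, [t_index]]
    counts = _loo_correct_counts(At, Bt, C, fold_scheme)
    return float(counts[0]) / (2 * A.shape[0])


def decode_timecourse(pool: SamplingPool, pair: Sequence[str],
                      cfg: DecodeConfig | None = None,
                      comparison: Optional[str] = None) -> DecodingTimecourse:
    """Iteration-averaged LOO decoding accuracy at every timepoint."""
    cfg = cfg or DecodeConfig()
    a, b = sorted(pair)
    accs = np.zeros((cfg.n_iterations, pool.times_ms.size))
    for pseudo in bootstrap_iterator(pool, cfg.n_iterations, cfg.base_seed,
                                     cfg.n_draw, cfg.n_means, cfg.zscore_axis):
        _, _, A, B = _class_arrays(pseudo, (a, b))
        counts = _loo_correct_counts(A, B, cfg.C, cfg.fold_scheme)
        accs[pseudo.iteration_index] = counts / (2 * A.shape[0])
    return DecodingTimecourse(
        participant_id=pool.participant_id,
        comparison=comparison or f"{a}_vs_{b}",
        times_ms=np.asarray(pool.times_ms),
        accuracy=accs.mean(axis=0),
        n_iterations=cfg.n_iterations,
        fold_scheme=cfg.fold_scheme,
        seed=cfg.base_seed,
        per_iteration=accs if cfg.keep_iterations else None,
    )


# ---------------------------------------------------------------------------
# pooled and cross-trained variants


def pool_conditions(pool: SamplingPool, scheme: str) -> SamplingPool:
    """Merge the four conditions into two balanced superclasses.

    ``direction_pooled``: TOWARD = {CD_TOWARD, IOVD_TOWARD} vs AWAY;
    ``cue_pooled``: CD = {CD_TOWARD, CD_AWAY} vs IOVD.  Bootstrap draws from
    a superclass take equal numbers of epochs from each member condition.
    """
    if set(pool.labels) != set(MID_CONDITIONS):
        raise ValidationError(
            f"pooling requires the 4 conditions {MID_CONDITIONS}, got {pool.labels}"
        )
    one = {k: v[0] for k, v in pool.conditions.items()}
    if scheme == "direction_pooled":
        merged = {
            "TOWARD": [one["CD_TOWARD"], one["IOVD_TOWARD"]],
            "AWAY": [one["CD_AWAY"], one["IOVD_AWAY"]],
        }
    elif scheme == "cue_pooled":
        merged = {
            "CD": [one["CD_TOWARD"], one["CD_AWAY"]],
            "IOVD": [one["IOVD_TOWARD"], one["IOVD_AWAY"]],
        }
    else:
        raise ConfigurationError(f"unknown pooling scheme {scheme!r}")
    return SamplingPool(
        participant_id=pool.participant_id, conditions=merged,
        times_ms=pool.times_ms,
    )


def _direction_token(label: str) -> str:
    return label.rsplit("_", 1)[-1]


def cross_decode_timecourse(pool: SamplingPool, train_pair: Sequence[str],
                            test_pair: Sequence[str],
                            cfg: DecodeConfig | None = None,
                            comparison: Optional[str] = None) -> DecodingTimecourse:
    """Train on one condition pair, test on another sharing label semantics.

    Per iteration and timepoint the SVM is fit on all pseudo-epochs of the
    training pair and evaluated on all pseudo-epochs of the test pair (no
    fold overlap is possible by construction).
    """
    cfg = cfg or DecodeConfig()
    tr = sorted(train_pair, key=_direction_token)
    te = sorted(test_pair, key=_direction_token)
    if [_direction_token(x) for x in tr] != [_direction_token(x) for x in te]:
        raise ValidationError(
            f"train pair {train_pair} and test pair {test_pair} do not share "
            "label semantics"
        )
    accs = np.zeros((cfg.n_iterations, pool.times_ms.size))
    for pseudo in bootstrap_iterator(pool, cfg.n_iterations, cfg.base_seed,
                                     cfg.n_draw, cfg.n_means, cfg.zscore_axis):
        for lab in set(tr) | set(te):
            if lab not in pseudo.data:
                raise ValidationError(f"condition {lab!r} missing from pool")
        A_tr, B_tr = pseudo.data[tr[0]], pseudo.data[tr[1]]  # (m, d, T)
        A_te, B_te = pseudo.data[te[0]], pseudo.data[te[1]]
        m, d, T = A_tr.shape
        y = np.concatenate([-np.ones(m), np.ones(m)])
        X = np.moveaxis(np.concatenate([A_tr, B_tr], axis=0), 2, 0)  # (T, 2m, d)
        W, b = _solve_chunked(X, y, cfg.C)
        dec_a = np.einsum("td,mdt->mt", W, A_te) + b
        dec_b = np.einsum("td,mdt->mt", W, B_te) + b
        n_test = A_te.shape[0] + B_te.shape[0]
        accs[pseudo.iteration_index] = (
            (dec_a <= 0).sum(axis=0) + (dec_b > 0).sum(axis=0)
        ) / n_test
    return DecodingTimecourse(
        participant_id=pool.participant_id,
        comparison=comparison or f"{'+'.join(tr)}_to_{'+'.join(te)}",
        times_ms=np.asarray(pool.times_ms),
        accuracy=accs.mean(axis=0),
        n_iterations=cfg.n_iterations,
        fold_scheme="train-all/test-all",
        seed=cfg.base_seed,
        per_iteration=accs if cfg.keep_iterations else None,
    )


def relabel_and_decode(epochs: EpochSet, new_labels: Sequence,
                       cfg: DecodeConfig | None = None,
                       comparison: Optional[str] = None) -> DecodingTimecourse:
    """Run the identical machinery after relabeling epochs (control analyses).

    Unbalanced relabelings are warned about and balanced by stratified
    subsampling (seeded from the decode config).
    """
    cfg = cfg or DecodeConfig()
    new_labels = np.asarray(new_labels)
    if new_labels.shape[0] != epochs.n_epochs:
        raise ValidationError("new_labels length must match epoch count")
    classes, counts = np.unique(new_labels, return_counts=True)
    if classes.size != 2:
        raise ValidationError(f"need exactly 2 relabeled classes, got {classes.size}")
    data = epochs.data
    labels = new_labels
    if counts[0] != counts[1]:
        warnings.warn(
            f"unbalanced relabeling {dict(zip(classes.tolist(), counts.tolist()))}; "
            "balancing by stratified subsampling",
            RuntimeWarning,
            stacklevel=2,
        )
        n_keep = counts.min()
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.base_seed, spawn_key=(0xBA1A,))
        )
        keep = np.concatenate([
            np.flatnonzero(new_labels == c)[
                rng.permutation(np.count_nonzero(new_labels == c))[:n_keep]
            ]
            for c in classes
        ])
        keep.sort()
        data = data[keep]
        labels = new_labels[keep]
    relabeled = EpochSet(
        participant_id=epochs.participant_id, data=data, labels=labels,
        times_ms=epochs.times_ms, rate_hz=epochs.rate_hz,
    )
    pool = build_pool(relabeled)
    return decode_timecourse(pool, tuple(classes.tolist()), cfg,
                             comparison=comparison)
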