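"""Linear-SVM decoding: solver oracles, LOO folds, pooled/cross/relabel variants."""

import numpy as np
import pytest
from sklearn.svm import SVC

from middecode._svm import svm_fit_batch
from middecode import synth
from middecode.decode import (DecodeConfig, cross_decode_timecourse,
                              decode_timecourse, fit_linear_svm,
                              loo_accuracy_at_timepoint, pool_conditions,
                              relabel_and_decode)
from middecode.errors import ConfigurationError, ValidationError
from middecode.resample import PseudoEpochSet, SamplingPool, build_pool


def gaussian_pool(n_per=60, n_ch=8, n_t=10, sep=0.0, seed=0,
                  labels=("A", "B")):
    """Two-class pool; opposite-sign step of +/- sep/2 on channel 0 in the
    second half of the epoch (a constant offset would be removed by the
    per-channel z-scoring, so the signal must be temporally structured)."""
    rng = np.random.default_rng(seed)
    conds = {}
    for j, lab in enumerate(labels):
        x = rng.normal(size=(n_per, n_ch, n_t))
        x[:, 0, n_t // 2:] += (sep / 2.0) * (1.0 if j == 1 else -1.0)
        conds[lab] = [x]
    return SamplingPool("p0", conds, np.arange(n_t, dtype=float))


def make_pseudo(m=8, d=6, T=4, sep=0.0, seed=0, labels=("A", "B")):
    rng = np.random.default_rng(seed)
    data = {}
    for j, lab in enumerate(labels):
        x = rng.normal(size=(m, d, T))
        if j == 1:
            x[:, 0, :] += sep
        data[lab] = x
    return PseudoEpochSet(data=data, n_draw=1, iteration_index=0,
                          times_ms=np.arange(T, dtype=float))


# ---------------------------------------------------------------------------
# single-fit contract


def test_1d_symmetric_boundary():
    model = fit_linear_svm(np.array([[-1.0], [1.0]]), ["a", "b"])
    assert model.decision_value(np.array([[0.0]]))[0] == pytest.approx(0.0, abs=1e-9)
    assert model.predict(np.array([[0.5]]))[0] == "b"
    assert model.predict(np.array([[-0.5]]))[0] == "a"


def test_margin_matches_brute_force_direction_search():
    X = np.array([[0.0, 0.0], [1.0, 0.2], [3.0, 2.5], [2.2, 3.0]])
    y = np.array([0, 0, 1, 1])
    # oracle: exhaustive search over unit-norm directions, optimal offset
    best = -np.inf
    for theta in np.arange(0.0, np.pi, 2e-4):
        w = np.array([np.cos(theta), np.sin(theta)])
        proj = X @ w
        for sgn in (1.0, -1.0):
            lo = (sgn * proj)[y == 1].min()
            hi = (sgn * proj)[y == 0].max()
            best = max(best, (lo - hi) / 2.0)
    model = fit_linear_svm(X, y, C=1e6)  # hard margin
    solver_margin = 1.0 / np.linalg.norm(model.w)
    assert solver_margin == pytest.approx(best, abs=1e-3)


def test_identical_points_opposite_labels_give_no_separation():
    X = np.vstack([np.ones((4, 3)), np.ones((4, 3))])
    y = ["a"] * 4 + ["b"] * 4
    model = fit_linear_svm(X, y, C=1.0)
    assert np.abs(model.decision_value(np.ones((2, 3)))).max() < 1e-6


def test_single_class_errors():
    with pytest.raises(ValidationError):
        fit_linear_svm(np.ones((3, 2)), ["a", "a", "a"])


def test_tie_predicts_lower_sorted_class():
    model = fit_linear_svm(np.array([[-1.0], [1.0]]), ["b", "a"])
    assert tuple(model.classes) == ("a", "b")
    pred = model.predict(np.array([[0.0]]))  # decision value exactly 0
    assert pred[0] == "a"


# ---------------------------------------------------------------------------
# batched solver vs libsvm


def test_batch_solver_agrees_with_svc(rng):
    B, n, d = 150, 30, 12
    y = np.concatenate([-np.ones(15), np.ones(15)])
    X = rng.normal(size=(B, n, d))
    X[:, y == 1, :] += 0.5 * rng.normal(size=(B, 1, d))
    Xt = rng.normal(size=(B, 8, d))
    W, b = svm_fit_batch(X, y)  # default (production) convergence settings
    pred = np.sign(np.einsum("bkd,bd->bk", Xt, W) + b[:, None])
    Wf, bf = svm_fit_batch(X, y, max_sweeps=400, tol=1e-6)  # fully converged
    pred_f = np.sign(np.einsum("bkd,bd->bk", Xt, Wf) + bf[:, None])

    def hinge_obj(w, bb, Xb):
        m = 1 - y * (Xb @ w + bb)
        return 0.5 * w @ w + np.clip(m, 0, None).sum()

    agree = agree_f = conf_agree = conf_total = 0
    for bi in range(B):
        svc = SVC(kernel="linear", C=1.0, tol=1e-6).fit(X[bi], y)
        dec = svc.decision_function(Xt[bi])
        p = np.where(dec > 0, 1, -1)
        agree += (p == pred[bi]).sum()
        agree_f += (p == pred_f[bi]).sum()
        confident = np.abs(dec) > 0.1  # points not sitting on the boundary
        conf_agree += (p[confident] == pred_f[bi][confident]).sum()
        conf_total += confident.sum()
        ours = hinge_obj(Wf[bi], bf[bi], X[bi])
        ref = hinge_obj(svc.coef_[0], svc.intercept_[0], X[bi])
        assert ours <= 1.05 * ref + 1e-6  # near-optimal hinge objective
    # converged: algorithmically equivalent to libsvm
    assert agree_f / (B * 8) > 0.99
    assert conf_agree / conf_total > 0.995
    # default sweep cap trades a little boundary precision for speed
    assert agree / (B * 8) > 0.93


def test_batch_solver_chunking_invariant(rng):
    X = rng.normal(size=(60, 20, 5))
    y = np.concatenate([-np.ones(10), np.ones(10)])
    W1, b1 = svm_fit_batch(X, y)
    W2a, b2a = svm_fit_batch(X[:17], y)
    W2b, b2b = svm_fit_batch(X[17:], y)
    assert np.array_equal(W1, np.concatenate([W2a, W2b]))
    assert np.array_equal(b1, np.concatenate([b2a, b2b]))


# ---------------------------------------------------------------------------
# leave-one-out accuracy


def _loo_oracle_counts(pseudo, pair, t, C=1.0, engine="batch"):
    """Independent fold-by-fold enumeration of the leave-one-per-class LOO."""
    a, b = sorted(pair)
    A, B = pseudo.data[a], pseudo.data[b]
    m = A.shape[0]
    correct = 0
    for k in range(m):
        tr = [i for i in range(m) if i != k]
        Xtr = np.concatenate([A[tr, :, t], B[tr, :, t]])
        ytr = np.array([-1.0] * (m - 1) + [1.0] * (m - 1))
        if engine == "batch":
            W, bias = svm_fit_batch(Xtr[None], ytr, C)
            w, bias = W[0], bias[0]
        else:
            svc = SVC(kernel="linear", C=C, tol=1e-6).fit(Xtr, ytr)
            w, bias = svc.coef_[0], float(svc.intercept_[0])
        correct += int(A[k, :, t] @ w + bias <= 0)
        correct += int(B[k, :, t] @ w + bias > 0)
    return correct


def test_loo_matches_explicit_fold_enumeration():
    pseudo = make_pseudo(m=8, d=6, T=3, sep=1.0, seed=4)
    for t in range(3):
        acc = loo_accuracy_at_timepoint(pseudo, ("A", "B"), t)
        assert acc == _loo_oracle_counts(pseudo, ("A", "B"), t) / 16
        # cross-check against the libsvm-based enumeration
        svc_acc = _loo_oracle_counts(pseudo, ("A", "B"), t, engine="svc") / 16
        assert abs(acc - svc_acc) <= 2 / 16


def test_loo_perfect_for_widely_separated_classes():
    pseudo = make_pseudo(m=6, d=4, T=2, sep=50.0, seed=1)
    assert loo_accuracy_at_timepoint(pseudo, ("A", "B"), 0) == 1.0


def test_loo_chance_for_uninformative_labels():
    accs = [loo_accuracy_at_timepoint(make_pseudo(m=10, d=8, T=1, sep=0.0,
                                                  seed=s), ("A", "B"), 0)
            for s in range(40)]
    # 99% binomial band around 0.5 for 40 x 20 test classifications
    half_width = 2.58 * np.sqrt(0.25 / (40 * 20))
    assert abs(np.mean(accs) - 0.5) < half_width + 0.01


def test_loo_t_index_out_of_range():
    with pytest.raises(ValidationError):
        loo_accuracy_at_timepoint(make_pseudo(T=3), ("A", "B"), 5)


def test_loo_leave_one_out_scheme_trains_on_41():
    pseudo = make_pseudo(m=21, d=4, T=1, sep=2.0, seed=2)
    acc = loo_accuracy_at_timepoint(pseudo, ("A", "B"), 0,
                                    fold_scheme="leave-one-out")
    assert 0.5 <= acc <= 1.0


# ---------------------------------------------------------------------------
# timecourse decoding


def test_decode_timecourse_shape_and_window():
    # information only exists on channel 0 from t >= 5
    n_t = 10
    pool = gaussian_pool(sep=4.0, n_t=n_t, seed=0)
    cfg = DecodeConfig(n_iterations=4, n_draw=5, n_means=8, base_seed=3)
    tc = decode_timecourse(pool, ("A", "B"), cfg)
    assert tc.accuracy.shape == (n_t,)
    assert np.all((tc.accuracy >= 0) & (tc.accuracy <= 1))
    assert tc.accuracy[n_t // 2:].mean() > 0.9
    assert abs(tc.accuracy[: n_t // 2].mean() - 0.5) < 0.2


def test_decode_channel_permutation_invariance():
    pool = gaussian_pool(sep=1.0, seed=5)
    cfg = DecodeConfig(n_iterations=2, n_draw=5, n_means=8, base_seed=1)
    base = decode_timecourse(pool, ("A", "B"), cfg).accuracy
    perm = np.random.default_rng(0).permutation(8)
    pool_p = SamplingPool("p0", {k: [v[0][:, perm, :]]
                                 for k, v in pool.conditions.items()},
                          pool.times_ms)
    assert np.array_equal(base, decode_timecourse(pool_p, ("A", "B"), cfg).accuracy)


def test_decode_scale_invariance_through_zscoring():
    pool = gaussian_pool(sep=1.0, seed=6)
    pool_scaled = SamplingPool("p0", {k: [1000.0 * v[0]]
                                      for k, v in pool.conditions.items()},
                               pool.times_ms)
    cfg = DecodeConfig(n_iterations=2, n_draw=5, n_means=8, base_seed=2)
    a = decode_timecourse(pool, ("A", "B"), cfg).accuracy
    b = decode_timecourse(pool_scaled, ("A", "B"), cfg).accuracy
    assert np.allclose(a, b)


def test_accuracy_monotonic_in_separation():
    cfg = DecodeConfig(n_iterations=3, n_draw=5, n_means=8, base_seed=0)
    for seed in range(3):
        means = [decode_timecourse(gaussian_pool(sep=s, seed=seed),
                                   ("A", "B"), cfg).accuracy.mean()
                 for s in (0.0, 0.8, 2.0)]
        assert means[1] >= means[0] - 0.02
        assert means[2] >= means[1] - 0.02


def test_extra_noise_channels_keep_separable_case_perfect():
    pool = gaussian_pool(n_ch=4, sep=60.0, seed=7)
    noisy = SamplingPool(
        "p0",
        {k: [np.concatenate([v[0],
                             np.random.default_rng(1).normal(size=v[0].shape)],
                            axis=1)]
         for k, v in pool.conditions.items()},
        pool.times_ms)
    cfg = DecodeConfig(n_iterations=2, n_draw=5, n_means=6, base_seed=4)
    acc = decode_timecourse(noisy, ("A", "B"), cfg).accuracy
    assert np.all(acc[5:] == 1.0)  # signal window stays perfectly separable


# ---------------------------------------------------------------------------
# pooling


def test_pool_conditions_superclasses(preprocessed_small):
    pool = build_pool(preprocessed_small)
    d = pool_conditions(pool, "direction_pooled")
    assert set(d.labels) == {"TOWARD", "AWAY"}
    assert d.pool_size == 2 * pool.pool_size
    assert len(d.conditions["TOWARD"]) == 2
    c = pool_conditions(pool, "cue_pooled")
    assert set(c.labels) == {"CD", "IOVD"}
    with pytest.raises(ConfigurationError):
        pool_conditions(pool, "bogus")


def test_pooled_draws_balanced_across_members(rng):
    from middecode.resample import draw_mean_epochs

    # members tagged with distinct constants: a balanced 2+2 draw always
    # averages to (c1 + c2) / 2
    m1 = np.full((40, 1, 4), 10.0) + rng.normal(0, 1e-9, size=(40, 1, 4))
    m2 = np.full((40, 1, 4), 30.0) + rng.normal(0, 1e-9, size=(40, 1, 4))
    pool = SamplingPool("p", {"S": [m1, m2]}, np.arange(4.0))
    ps = draw_mean_epochs(pool, n_draw=4, n_means=10, seed=0, standardize=False)
    assert np.allclose(ps.data["S"], 20.0, atol=1e-6)
    with pytest.raises(ValidationError):
        draw_mean_epochs(pool, n_draw=3, n_means=2)  # 3 not divisible by 2


# ---------------------------------------------------------------------------
# cross-trained decoding


def four_condition_pool(shared=0.0, unique=3.0, n_per=60, n_ch=8, n_t=6, seed=0):
    """CD pair separated on ch 1, IOVD pair on ch 2, shared signal on ch 3.

    Signals are second-half steps so they survive per-channel z-scoring.
    """
    rng = np.random.default_rng(seed)
    half = n_t // 2
    conds = {}
    for lab in synth.MID_CONDITIONS:
        x = rng.normal(size=(n_per, n_ch, n_t))
        sign = 1.0 if lab.endswith("TOWARD") else -1.0
        ch = 1 if lab.startswith("CD") else 2
        x[:, ch, half:] += sign * unique
        x[:, 3, half:] += sign * shared
        conds[lab] = [x]
    return SamplingPool("p0", conds, np.arange(n_t, dtype=float))


def test_cross_decoding_transfers_only_shared_information():
    cfg = DecodeConfig(n_iterations=4, n_draw=5, n_means=8, base_seed=8)
    with_shared = cross_decode_timecourse(
        four_condition_pool(shared=3.0), ("CD_TOWARD", "CD_AWAY"),
        ("IOVD_TOWARD", "IOVD_AWAY"), cfg)
    # transfer only inside the shared-signal window (second half)
    assert with_shared.accuracy[3:].mean() > 0.9
    without = cross_decode_timecourse(
        four_condition_pool(shared=0.0), ("CD_TOWARD", "CD_AWAY"),
        ("IOVD_TOWARD", "IOVD_AWAY"), cfg)
    assert abs(without.accuracy.mean() - 0.5) < 0.12


def test_cross_train_equals_test_is_resubstitution_bound():
    pool = four_condition_pool(shared=0.0, unique=1.0, seed=3)
    cfg = DecodeConfig(n_iterations=3, n_draw=5, n_means=8, base_seed=5)
    resub = cross_decode_timecourse(pool, ("CD_TOWARD", "CD_AWAY"),
                                    ("CD_TOWARD", "CD_AWAY"), cfg)
    loo = decode_timecourse(pool, ("CD_TOWARD", "CD_AWAY"), cfg)
    assert resub.accuracy.mean() >= loo.accuracy.mean() - 0.02


def test_cross_semantics_mismatch_errors():
    pool = four_condition_pool()
    with pytest.raises(ValidationError):
        cross_decode_timecourse(pool, ("CD_TOWARD", "CD_AWAY"),
                                ("CD_AWAY", "IOVD_AWAY"),
                                DecodeConfig(n_iterations=1))


# ---------------------------------------------------------------------------
# relabeling


def test_relabel_with_true_labels_reproduces_decoding(preprocessed_small):
    sub = preprocessed_small
    keep = np.isin(sub.labels, ["CD_TOWARD", "CD_AWAY"])
    import dataclasses

    two = dataclasses.replace(sub, data=sub.data[keep], labels=sub.labels[keep])
    cfg = DecodeConfig(n_iterations=2, n_draw=5, n_means=6, base_seed=6)
    direct = decode_timecourse(build_pool(two), ("CD_TOWARD", "CD_AWAY"), cfg)
    relabeled = relabel_and_decode(two, two.labels, cfg)
    assert np.array_equal(direct.accuracy, relabeled.accuracy)


def test_relabel_shuffled_labels_give_chance(preprocessed_small):
    sub = preprocessed_small
    rng = np.random.default_rng(11)
    shuffled = rng.permutation(np.where(
        np.arange(sub.n_epochs) % 2 == 0, "X", "Y"))
    cfg = DecodeConfig(n_iterations=6, n_draw=5, n_means=4, base_seed=7)
    tc = relabel_and_decode(sub, shuffled, cfg)
    assert abs(tc.accuracy.mean() - 0.5) < 0.08


def test_relabel_unbalanced_warns_and_balances(preprocessed_small):
    sub = preprocessed_small
    labels = np.array(["X"] * 30 + ["Y"] * 10)
    cfg = DecodeConfig(n_iterations=1, n_draw=4, n_means=2, base_seed=1)
    with pytest.warns(RuntimeWarning, match="unbalanced"):
        tc = relabel_and_decode(sub, labels, cfg)
    assert tc.accuracy.shape == (sub.data.shape[-1],)


def test_relabel_length_mismatch_errors(preprocessed_small):
    with pytest.raises(ValidationError):
        relabel_and_decode(preprocessed_small, np.array(["X", "Y"]),
                           DecodeConfig(n_iterations=1))
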