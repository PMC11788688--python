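"""Validation statistics against independent oracles and hand fixtures."""

import numpy as np
import pytest

from sbrt_tcp.stats import (
    StatsError,
    calibration_plot_data,
    confusion_at,
    delong_paired_test,
    hosmer_lemeshow,
    roc_auc,
    select_criterion,
)

# -- independent oracles -----------------------------------------------------


def auc_pairwise_oracle(scores, labels):
    """Exhaustive pairwise concordance: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def delong_oracle(scores_a, scores_b, labels):
    """Direct loop-based DeLong structural components for two paired score sets.

    Returns (auc_a, auc_b, var_a, var_b, cov_ab) computed from the
    definitions, independent of the vectorised implementation.
    """

    def psi(x, y):
        return 1.0 if x > y else (0.5 if x == y else 0.0)

    def comps(scores):
        pos = [s for s, y in zip(scores, labels) if y == 1]
        neg = [s for s, y in zip(scores, labels) if y == 0]
        m, n = len(pos), len(neg)
        v10 = [sum(psi(x, y) for y in neg) / n for x in pos]
        v01 = [sum(psi(x, y) for x in pos) / m for y in neg]
        auc = sum(v10) / m
        return auc, v10, v01, m, n

    def svar(v, mean):
        return sum((x - mean) ** 2 for x in v) / (len(v) - 1)

    def scov(u, v, mu, mv):
        return sum((a - mu) * (b - mv) for a, b in zip(u, v)) / (len(u) - 1)

    auc_a, v10a, v01a, m, n = comps(scores_a)
    auc_b, v10b, v01b, _, _ = comps(scores_b)
    var_a = svar(v10a, auc_a) / m + svar(v01a, auc_a) / n
    var_b = svar(v10b, auc_b) / m + svar(v01b, auc_b) / n
    cov = scov(v10a, v10b, auc_a, auc_b) / m + scov(v01a, v01b, auc_a, auc_b) / n
    return auc_a, auc_b, var_a, var_b, cov


# -- roc_auc -----------------------------------------------------------------


def test_auc_perfect_separation():
    r = roc_auc([0.1, 0.9], [0, 1])
    assert r.auc == 1.0
    assert r.fpr[0] == 0.0 and r.tpr[-1] == 1.0


def test_auc_all_ties_is_half():
    r = roc_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
    assert r.auc == 0.5
    assert r.criterion.degenerate


def test_auc_hand_example():
    # pairs: (0.4>0.2)=1, (0.4<0.6)=0, (0.8>0.2)=1, (0.8>0.6)=1 -> 3/4
    r = roc_auc([0.2, 0.4, 0.6, 0.8], [0, 1, 0, 1])
    assert r.auc == pytest.approx(0.75)


def test_auc_equals_pairwise_concordance_on_random_fixtures(rng):
    for _ in range(100):
        n = int(rng.integers(4, 51))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if labels.min() == labels.max():
            continue
        assert roc_auc(scores, labels).auc == pytest.approx(
            auc_pairwise_oracle(scores, labels), abs=1e-12
        )


def test_auc_curve_monotone(rng):
    scores = rng.random(200)
    labels = (rng.random(200) < 0.4).astype(int)
    r = roc_auc(scores, labels)
    assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)
    assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0) and (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
    assert r.ci95[0] <= r.auc <= r.ci95[1]


def test_auc_input_validation():
    with pytest.raises(StatsError):
        roc_auc([0.1, 0.2], [1, 1])
    with pytest.raises(StatsError):
        roc_auc([0.1, np.nan], [0, 1])
    with pytest.raises(StatsError):
        roc_auc([0.1, 0.2], [0, 2])


# -- DeLong paired test ------------------------------------------------------


def test_delong_identical_scores_give_p_one():
    scores = [0.1, 0.4, 0.35, 0.8, 0.7, 0.2]
    labels = [0, 0, 1, 1, 1, 0]
    z, p, diff = delong_paired_test(scores, scores, labels)
    assert (z, p, diff) == (0.0, 1.0, 0.0)


def test_delong_antisymmetric(rng):
    a, b = rng.random(30), rng.random(30)
    y = (rng.random(30) < 0.5).astype(int)
    y[:2] = [0, 1]
    za, pa, da = delong_paired_test(a, b, y)
    zb, pb, db = delong_paired_test(b, a, y)
    assert za == pytest.approx(-zb) and pa == pytest.approx(pb) and da == pytest.approx(-db)


def test_delong_flipped_scores_aucs_sum_to_one(rng):
    a = rng.random(40)
    y = (rng.random(40) < 0.5).astype(int)
    y[:2] = [0, 1]
    auc_a = roc_auc(a, y).auc
    auc_b = roc_auc(1.0 - a, y).auc
    assert auc_a + auc_b == pytest.approx(1.0)
    z, p, diff = delong_paired_test(a, 1.0 - a, y)
    assert diff == pytest.approx(2.0 * auc_a - 1.0)


def test_delong_variance_matches_oracle_on_small_fixtures(rng):
    for _ in range(20):
        a = np.round(rng.random(8), 2)
        b = np.round(rng.random(8), 2)
        y = np.array([0, 0, 0, 1, 1, 1, 1, 0])
        auc_a, auc_b, var_a, var_b, cov = delong_oracle(a, b, y)
        ra = roc_auc(a, y)
        assert ra.auc == pytest.approx(auc_a, abs=1e-12)
        assert ra.variance == pytest.approx(var_a, abs=1e-12)
        z, p, diff = delong_paired_test(a, b, y)
        var_diff = var_a + var_b - 2 * cov
        assert diff == pytest.approx(auc_a - auc_b, abs=1e-12)
        if var_diff > 1e-16:
            assert z == pytest.approx((auc_a - auc_b) / np.sqrt(var_diff), abs=1e-10)


def test_delong_length_mismatch():
    with pytest.raises(StatsError):
        delong_paired_test([0.1, 0.2, 0.3], [0.1, 0.2], [0, 1, 1])


# -- Hosmer-Lemeshow ---------------------------------------------------------


def test_hl_two_bin_hand_example():
    # bin1: 50 patients at p=0.2 with 10 events; bin2: 50 at p=0.8 with 40.
    # O = E in both cells of both bins -> chi-square exactly 0.
    pred = np.array([0.2] * 50 + [0.8] * 50)
    obs = np.array([1] * 10 + [0] * 40 + [1] * 40 + [0] * 10)
    res = hosmer_lemeshow(pred, obs, n_bins=2)
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)
    assert res.n_bins_effective == 2
    assert res.bins["n"].sum() == 100


def test_hl_constant_predictions_collapse_to_one_bin():
    pred = np.full(40, 0.5)
    obs = np.array([0, 1] * 20)
    res = hosmer_lemeshow(pred, obs, n_bins=10)
    assert res.n_bins_effective == 1
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)


def test_hl_two_bin_nonzero_hand_value():
    # bin1: E = 10, O = 15; bin2: E = 40, O = 35 (n = 50 each)
    # chi2 = 25/10 + 25/40 + 25/40 + 25/10 = 6.25
    pred = np.array([0.2] * 50 + [0.8] * 50)
    obs = np.array([1] * 15 + [0] * 35 + [1] * 35 + [0] * 15)
    res = hosmer_lemeshow(pred, obs, n_bins=2)
    assert res.chi_square == pytest.approx(6.25, abs=1e-12)
    assert res.df == 2  # external-validation convention: df = bins


def test_hl_fitted_df_policy():
    pred = np.linspace(0.05, 0.95, 200)
    obs = (np.arange(200) % 3 == 0).astype(int)
    ext = hosmer_lemeshow(pred, obs, n_bins=10, df_policy="external")
    fit = hosmer_lemeshow(pred, obs, n_bins=10, df_policy="fitted")
    assert ext.chi_square == fit.chi_square
    assert ext.df == 10 and fit.df == 8
    assert fit.p_value <= ext.p_value  # same statistic, fewer df


def test_hl_merges_degenerate_bins():
    # a clump of ~0 predictions produces an expected-event count of ~0,
    # which must be merged rather than divided by
    pred = np.concatenate([np.full(30, 1e-15), np.linspace(0.2, 0.9, 70)])
    obs = (pred > 0.5).astype(int)
    res = hosmer_lemeshow(pred, obs, n_bins=10)
    assert res.merged >= 1
    assert np.isfinite(res.chi_square)
    assert res.bins["n"].sum() == 100


def test_hl_input_validation():
    with pytest.raises(StatsError):
        hosmer_lemeshow([0.2, 1.4, 0.5] * 10, [0, 1, 0] * 10)
    with pytest.raises(StatsError):
        hosmer_lemeshow([0.2] * 5, [0, 1, 0, 1, 0], n_bins=10)


def test_calibration_flags_follow_sidedness_convention():
    pred = np.array([0.2] * 50 + [0.8] * 50)
    obs = np.array([1] * 30 + [0] * 20 + [1] * 30 + [0] * 20)  # both bins observe 0.6
    res = calibration_plot_data(pred, obs, n_bins=2)
    # bin predicted 0.2 < observed 0.6: model conservative -> "under";
    # bin predicted 0.8 > observed 0.6 -> "over"
    assert list(res.bins["flag"]) == ["under", "over"]
    flipped = calibration_plot_data(1.0 - pred, 1 - obs, n_bins=2)
    assert list(flipped.bins["flag"]) == ["under", "over"]  # complement symmetry
    perfect = calibration_plot_data(
        np.array([0.2] * 50 + [0.8] * 50),
        np.array(([1] * 10 + [0] * 40) + ([1] * 40 + [0] * 10)),
        n_bins=2,
    )
    assert list(perfect.bins["flag"]) == ["ok", "ok"]


# -- operating point ---------------------------------------------------------


def test_select_criterion_enumerated_example():
    # cutpoints at observed scores; >=0.6 separates perfectly
    crit = select_criterion([0.2, 0.4, 0.6, 0.8], [0, 0, 1, 1])
    assert 0.4 < crit.threshold <= 0.6
    assert crit.youden_index == pytest.approx(1.0)


def test_select_criterion_perfectly_separated_lies_in_gap():
    crit = select_criterion([0.1, 0.2, 0.7, 0.9], [0, 0, 1, 1])
    assert 0.2 < crit.threshold <= 0.7


def test_select_criterion_tie_breaks_toward_higher_threshold():
    # thresholds 0.3 and 0.7 both give Youden = 0.5; the higher must win
    scores = [0.1, 0.3, 0.7, 0.9]
    labels = [0, 1, 0, 1]
    crit = select_criterion(scores, labels)
    assert crit.threshold == pytest.approx(0.9)


def test_confusion_threshold_zero_predicts_all_positive(rng):
    scores = rng.random(50)
    labels = (rng.random(50) < 0.5).astype(int)
    labels[:2] = [0, 1]
    cm = confusion_at(scores, labels, 0.0)
    assert cm.fn == 0 and cm.tn == 0
    assert cm.sensitivity_pct == 100.0 and cm.specificity_pct == 0.0


def test_confusion_hand_fixture():
    scores = [0.9, 0.8, 0.6, 0.4, 0.3, 0.1]
    labels = [1, 1, 0, 1, 0, 0]
    cm = confusion_at(scores, labels, 0.5)
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 1, 1, 2)
    assert cm.accuracy_pct == pytest.approx(100 * 4 / 6)
    assert cm.total == 6


def test_confusion_threshold_out_of_range():
    with pytest.raises(StatsError):
        confusion_at([0.2, 0.8], [0, 1], 1.5)


def test_operating_point_consistency(rng):
    # roc_auc's reported sensitivity/specificity are exactly confusion_at's
    # at the selected criterion
    scores = np.round(rng.random(80), 2)
    labels = (rng.random(80) < 0.5).astype(int)
    labels[:2] = [0, 1]
    r = roc_auc(scores, labels)
    cm = confusion_at(scores, labels, r.criterion.threshold)
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (
        r.confusion.tp, r.confusion.fp, r.confusion.fn, r.confusion.tn,
    )
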