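"""Metric correctness against brute-force oracles and hand-worked fixtures."""

import numpy as np
import pytest
from scipy import stats

from mmsurv.survival_metrics import (auroc_delong, bootstrap_cindex,
                                     compare_cindex, delong_test,
                                     harrell_cindex, km_estimate,
                                     label_at_horizon, logrank_test,
                                     median_split, EXCLUDED, NEGATIVE, POSITIVE)
from conftest import random_survival


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)


def cindex_oracle(risks, time, event):
    conc = pairs = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # i must be the earlier patient and an event
            if not event[i]:
                continue
            if time[i] > time[j]:
                continue
            if time[i] == time[j] and event[j]:
                continue  # tied event times are not comparable
            pairs += 1
            if risks[i] > risks[j]:
                conc += 1
            elif risks[i] == risks[j]:
                conc += 0.5
    return conc / pairs, int(pairs)


def auc_oracle(pos, neg):
    s = 0.0
    for p in pos:
        for q in neg:
            s += 1.0 if p > q else (0.5 if p == q else 0.0)
    return s / (len(pos) * len(neg))


def km_oracle(time, event):
    """Plain product-limit computed at each distinct event time."""
    times = np.unique(time[event.astype(bool)])
    s, out = 1.0, []
    for t in times:
        n_at_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        s *= 1.0 - d / n_at_risk
        out.append((t, s))
    return out


def logrank_oracle(time_a, event_a, time_b, event_b):
    time = np.concatenate([time_a, time_b])
    event = np.concatenate([event_a, event_b])
    grp = np.concatenate([np.zeros(len(time_a)), np.ones(len(time_b))])
    o_minus_e = v = 0.0
    for t in np.unique(time[event.astype(bool)]):
        at = time >= t
        n, n1 = at.sum(), (at & (grp == 0)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (grp == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e ** 2 / v
    return chi2, stats.chi2.sf(chi2, 1)


# ---------------------------------------------------------------------------
# hand-worked fixtures


def test_cindex_four_patient_fixture():
    """3 of 4 comparable pairs concordant -> C = 0.75."""
    res = harrell_cindex([0.9, 0.8, 0.2, 0.3], [2, 4, 6, 8], [1, 0, 1, 1])
    assert res.point == pytest.approx(0.75)
    assert res.n_comparable_pairs == 4


def test_cindex_perfect_and_tied():
    t = np.array([3.0, 1.0, 2.0, 5.0])
    assert harrell_cindex(-t, t, np.ones(4)).point == 1.0
    assert harrell_cindex(np.zeros(4), t, np.ones(4)).point == 0.5


def test_km_three_patient_fixture():
    times, surv = km_estimate([1, 2, 3], [1, 1, 0])
    lookup = dict(zip(times, surv))
    assert lookup[1.0] == pytest.approx(2 / 3)
    assert lookup[2.0] == pytest.approx(1 / 3)
    assert surv[-1] == pytest.approx(1 / 3)  # censoring does not move the curve


def test_km_degenerate_cases():
    rng = np.random.default_rng(0)
    t = rng.exponential(5, 30)
    # no censoring: S(t) = empirical survivor fraction at each event time
    times, surv = km_estimate(t, np.ones(30))
    for tt, ss in zip(times[1:], surv[1:]):
        assert ss == pytest.approx(np.mean(t > tt))
    _, surv_c = km_estimate(t, np.zeros(30))
    assert np.all(surv_c == 1.0)


def test_logrank_two_by_two_fixture():
    """O1 = 2, E1 = 5/6, V = 17/36 -> chi2 = 49/17."""
    chi2, p = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
    assert chi2 == pytest.approx(49 / 17, rel=1e-9)
    assert 0 < p < 1


def test_logrank_identical_groups_and_no_events():
    t, e = [1.0, 2.0, 3.0], [1, 0, 1]
    chi2, p = logrank_test(t, e, t, e)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        logrank_test([1, 2], [0, 0], [3, 4], [0, 0])


# ---------------------------------------------------------------------------
# oracle agreement on random instances


def test_cindex_matches_bruteforce_oracle():
    rng = np.random.default_rng(1)
    for k in range(120):
        n = int(rng.integers(5, 50))
        risks, time, event = random_survival(rng, n, tie_prob=0.5 if k % 2 else 0.0)
        if k % 3 == 0:
            risks = np.round(risks)  # risk ties
        try:
            mine = harrell_cindex(risks, time, event)
        except ValueError:
            continue
        c, pairs = cindex_oracle(risks, time, event)
        assert mine.point == pytest.approx(c, abs=1e-10)
        assert mine.n_comparable_pairs == pairs


def test_auroc_matches_pair_enumeration():
    rng = np.random.default_rng(2)
    for k in range(120):
        n = int(rng.integers(4, 50))
        scores = np.round(rng.standard_normal(n), 1 if k % 2 else 6)
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.sum() in (0, n):
            continue
        res = auroc_delong(scores, labels)
        assert res.auc == pytest.approx(
            auc_oracle(scores[labels == 1], scores[labels == 0]), abs=1e-10)


def test_km_matches_product_limit_oracle():
    rng = np.random.default_rng(3)
    for _ in range(100):
        n = int(rng.integers(3, 50))
        _, time, event = random_survival(rng, n, tie_prob=0.5)
        times, surv = km_estimate(time, event)
        lookup = dict(zip(times, surv))
        for t, s in km_oracle(time, event):
            assert lookup[t] == pytest.approx(s, abs=1e-9)


def test_logrank_matches_counting_process_oracle():
    rng = np.random.default_rng(4)
    for _ in range(100):
        na, nb = int(rng.integers(3, 30)), int(rng.integers(3, 30))
        _, ta, ea = random_survival(rng, na, tie_prob=0.5)
        _, tb, eb = random_survival(rng, nb, tie_prob=0.5)
        chi2, p = logrank_test(ta, ea, tb, eb)
        chi2_o, p_o = logrank_oracle(ta, ea, tb, eb)
        assert chi2 == pytest.approx(chi2_o, abs=1e-8)
        assert p == pytest.approx(p_o, abs=1e-8)


# ---------------------------------------------------------------------------
# bootstrap and comparison test


def test_bootstrap_degenerate_and_deterministic():
    t = np.arange(1.0, 9.0)
    r = -t
    res = bootstrap_cindex(r, t, np.ones(8), B=50, seed=5)
    assert res.ci == (1.0, 1.0)
    rng = np.random.default_rng(9)
    risks, time, event = random_survival(rng, 40)
    a = bootstrap_cindex(risks, time, event, B=100, seed=3)
    b = bootstrap_cindex(risks, time, event, B=100, seed=3)
    assert np.array_equal(a.replicates, b.replicates) and a.ci == b.ci


def test_bootstrap_ci_narrows_with_sample_size():
    widths = {80: [], 160: []}
    for seed in range(10):
        rng = np.random.default_rng(seed)
        for n in widths:
            risks, time, event = random_survival(rng, n, censor_frac=0.3)
            risks = risks - 0.5 * time  # informative risk
            res = bootstrap_cindex(risks, time, event, B=200, seed=seed)
            widths[n].append(res.ci[1] - res.ci[0])
    assert np.mean(widths[160]) < np.mean(widths[80])


def test_compare_cindex_null_separation_and_oracle():
    a = bootstrap_cindex([3, 2, 1], [1, 2, 3], [1, 1, 1], B=20, seed=0)
    t, p = compare_cindex(a, a)
    assert (t, p) == (0.0, 1.0)
    rng = np.random.default_rng(7)
    x = bootstrap_cindex(*random_survival(rng, 50), B=100, seed=1)
    y = bootstrap_cindex(*random_survival(rng, 50), B=100, seed=2)
    t, p = compare_cindex(x, y)
    t_o, p_o = stats.ttest_ind(x.replicates, y.replicates, equal_var=False)
    assert t == pytest.approx(t_o) and p == pytest.approx(p_o)


# ---------------------------------------------------------------------------
# horizon labels, DeLong variance, stratification


def test_label_at_horizon_rules_and_partition():
    time = np.array([20.0, 30.0, 40.0, 36.0])
    event = np.array([1, 0, 1, 0])
    labels = label_at_horizon(time, event, 36.0)
    assert labels[0] == POSITIVE       # event before horizon
    assert labels[1] == EXCLUDED       # censored before horizon
    assert labels[2] == NEGATIVE       # event after horizon
    assert labels[3] == NEGATIVE       # censored exactly at horizon: survived to it
    rng = np.random.default_rng(11)
    _, t, e = random_survival(rng, 200)
    lab = label_at_horizon(t, e, 8.0)
    assert (lab == POSITIVE).sum() + (lab == NEGATIVE).sum() + (lab == EXCLUDED).sum() == 200


def test_delong_variance_close_to_bootstrap():
    rng = np.random.default_rng(21)
    n = 100
    labels = (rng.random(n) < 0.4).astype(int)
    scores = rng.standard_normal(n) + labels
    res = auroc_delong(scores, labels)
    reps = []
    for _ in range(2000):
        idx = rng.integers(0, n, n)
        lb, sc = labels[idx], scores[idx]
        if 0 < lb.sum() < n:
            reps.append(auroc_delong(sc, lb).auc)
    boot_var = np.var(reps, ddof=1)
    assert res.variance == pytest.approx(boot_var, rel=0.2)


def test_delong_perfect_separation_and_paired_test():
    labels = np.array([1, 1, 0, 0])
    res = auroc_delong([5.0, 4.0, 1.0, 0.0], labels)
    assert res.auc == 1.0 and res.variance == 0.0
    z, p = delong_test([5.0, 4.0, 1.0, 0.0], [5.0, 4.0, 1.0, 0.0], labels)
    assert p == 1.0
    rng = np.random.default_rng(13)
    n = 80
    lab = (rng.random(n) < 0.5).astype(int)
    a = rng.standard_normal(n) + 2 * lab
    b = rng.standard_normal(n)
    z, p = delong_test(a, b, lab)
    assert z > 0 and p < 0.05


def test_median_split_rules():
    res = median_split([1.0, 2.0, 3.0, 4.0])
    assert res.threshold == 2.5 and list(res.high_mask) == [False, False, True, True]
    res3 = median_split([1.0, 2.0, 3.0])
    assert list(res3.high_mask) == [False, False, True]
    allsame = median_split([1.0, 1.0, 1.0])
    assert allsame.degenerate and not allsame.high_mask.any()


def test_median_split_with_outcomes_runs_logrank():
    rng = np.random.default_rng(17)
    risks, time, event = random_survival(rng, 60, censor_frac=0.3)
    risks = risks - 0.3 * time
    res = median_split(risks, time, event)
    assert res.chi2 is not None and 0 <= res.p_value <= 1


# ---------------------------------------------------------------------------
# invariance properties


def test_rank_metrics_invariant_under_monotone_transform():
    rng = np.random.default_rng(19)
    risks, time, event = random_survival(rng, 60)
    c1 = harrell_cindex(risks, time, event).point
    c2 = harrell_cindex(np.exp(3 * risks), time, event).point
    assert c1 == pytest.approx(c2, abs=1e-12)
    labels = label_at_horizon(time, event, 8.0)
    if (labels == POSITIVE).any() and (labels == NEGATIVE).any():
        a1 = auroc_delong(risks, labels).auc
        a2 = auroc_delong(np.tanh(risks), labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)


def test_cindex_antisymmetry_without_ties():
    rng = np.random.default_rng(23)
    risks, time, event = random_survival(rng, 50)
    c = harrell_cindex(risks, time, event).point
    c_neg = harrell_cindex(-risks, time, event).point
    assert c + c_neg == pytest.approx(1.0, abs=1e-12)
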