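"""Censoring-aware evaluation of risk scores.

Implements Harrell's concordance index with percentile-bootstrap confidence
intervals and a Welch comparison test, Kaplan-Meier estimation and the
two-group log-rank test (via lifelines), median-risk stratification,
time-horizon binary labelling, and AUROC with DeLong variance, confidence
interval and paired test.

Conventions: risk ties in the C-index count 0.5; a patient censored before
the horizon is excluded from the horizon's AUROC; all p-values two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats


# ---------------------------------------------------------------------------
# Concordance


@dataclass
class CIndexResult:
    point: float
    n_comparable_pairs: int
    replicates: np.ndarray | None = None
    ci: tuple[float, float] | None = None
    n_redrawn: int = 0


def _concordance(risks: np.ndarray, time: np.ndarray, event: np.ndarray) -> tuple[float, int]:
    """Pairwise Harrell concordance. O(n^2) but vectorized; n here is small."""
    t = np.asarray(time, float)
    e = np.asarray(event, float).astype(bool)
    r = np.asarray(risks, float)
    # pair (i, j) comparable iff t_i < t_j and event_i, or t_i == t_j and exactly
    # one event (the event patient must be the "earlier" one)
    ti, tj = t[:, None], t[None, :]
    ei = e[:, None]
    comparable = (ti < tj) & ei
    # tied times: event vs censored is comparable (event counted as earlier)
    comparable |= (ti == tj) & ei & ~e[None, :]
    ri, rj = r[:, None], r[None, :]
    conc = np.where(ri > rj, 1.0, np.where(ri == rj, 0.5, 0.0))
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs (need at least one event before another follow-up)")
    return float((conc * comparable).sum() / n_pairs), n_pairs


def harrell_cindex(risks, time, event) -> CIndexResult:
    """Harrell's C: fraction of comparable pairs where the earlier-event
    patient has the higher risk; risk ties score 0.5."""
    if len(np.asarray(time)) < 2:
        raise ValueError("need at least two patients")
    c, n = _concordance(np.asarray(risks), np.asarray(time), np.asarray(event))
    return CIndexResult(point=c, n_comparable_pairs=n)


def bootstrap_cindex(risks, time, event, B: int = 1000, seed: int = 0) -> CIndexResult:
    """Percentile-bootstrap CI of Harrell's C (patients resampled with
    replacement). Replicates with no comparable pairs are redrawn."""
    risks = np.asarray(risks, float)
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    base = harrell_cindex(risks, time, event)
    rng = np.random.default_rng(seed)
    n = len(time)
    reps = np.empty(B)
    redrawn = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                reps[b], _ = _concordance(risks[idx], time[idx], event[idx])
                break
            except ValueError:
                redrawn += 1
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return CIndexResult(
        point=base.point,
        n_comparable_pairs=base.n_comparable_pairs,
        replicates=reps,
        ci=(float(lo), float(hi)),
        n_redrawn=redrawn,
    )


def compare_cindex(a: CIndexResult, b: CIndexResult) -> tuple[float, float]:
    """Welch unpaired t-test on two bootstrap replicate vectors."""
    if a.replicates is None or b.replicates is None:
        raise ValueError("both results must carry bootstrap replicates")
    x, y = a.replicates, b.replicates
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:  # degenerate: identical-constant replicates
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.inf if x.mean() > y.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Kaplan-Meier, log-rank, stratification


def km_estimate(time, event) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate; returns (times, S(t)) as a
    right-continuous step function starting at S(0)=1."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, float), np.asarray(event, float))
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic df=1, p-value)."""
    ea, eb = np.asarray(event_a, float), np.asarray(event_b, float)
    if len(time_a) == 0 or len(time_b) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test undefined with no events")
    res = _ll_logrank(np.asarray(time_a, float), np.asarray(time_b, float), ea, eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class StratificationResult:
    threshold: float
    high_mask: np.ndarray
    chi2: float | None = None
    p_value: float | None = None
    km_high: tuple[np.ndarray, np.ndarray] | None = None
    km_low: tuple[np.ndarray, np.ndarray] | None = None
    degenerate: bool = False


def median_split(risks, time=None, event=None) -> StratificationResult:
    """Split at the median risk: high-risk iff risk > median (ties at the
    median go to the low-risk group). With outcomes supplied, also computes
    per-group KM curves and the log-rank test."""
    risks = np.asarray(risks, float)
    if len(risks) < 2:
        raise ValueError("need at least two patients to stratify")
    thr = float(np.median(risks))
    high = risks > thr
    res = StratificationResult(threshold=thr, high_mask=high, degenerate=not high.any())
    if time is not None and event is not None and high.any() and (~high).any():
        time = np.asarray(time, float)
        event = np.asarray(event, float)
        res.chi2, res.p_value = logrank_test(time[high], event[high], time[~high], event[~high])
        res.km_high = km_estimate(time[high], event[high])
        res.km_low = km_estimate(time[~high], event[~high])
    return res


# ---------------------------------------------------------------------------
# Time-horizon labels and DeLong AUROC

POSITIVE, NEGATIVE, EXCLUDED = 1, 0, -1


def label_at_horizon(time, event, horizon: float) -> np.ndarray:
    """Binary status at a follow-up horizon (months): positive if the event
    occurred by the horizon, excluded if censored before it, else negative."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    time = np.asarray(time, float)
    event = np.asarray(event, float).astype(bool)
    labels = np.full(time.shape, NEGATIVE, dtype=int)
    labels[event & (time <= horizon)] = POSITIVE
    labels[~event & (time < horizon)] = EXCLUDED
    return labels


@dataclass
class AUROCResult:
    auc: float
    variance: float
    ci: tuple[float, float]
    n_pos: int
    n_neg: int
    # per-observation structural components, kept for the paired test
    v_pos: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    v_neg: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v_pos = (all_r[:m] - r_pos) / n          # V10: one per positive
    v_neg = 1.0 - (all_r[m:] - r_neg) / m    # V01: one per negative
    return float(auc), v_pos, v_neg


def auroc_delong(risks, labels: np.ndarray) -> AUROCResult:
    """AUC via the Mann-Whitney rank statistic with DeLong variance and a
    normal-approximation 95% CI truncated to [0, 1].

    ``labels`` uses the label_at_horizon convention; excluded patients are
    ignored.
    """
    risks = np.asarray(risks, float)
    labels = np.asarray(labels, int)
    pos = risks[labels == POSITIVE]
    neg = risks[labels == NEGATIVE]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUROC needs at least one positive and one negative")
    auc, v_pos, v_neg = _delong_components(pos, neg)
    var = 0.0
    if len(pos) > 1:
        var += v_pos.var(ddof=1) / len(pos)
    if len(neg) > 1:
        var += v_neg.var(ddof=1) / len(neg)
    se = np.sqrt(var)
    z = stats.norm.ppf(0.975)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return AUROCResult(auc=auc, variance=float(var), ci=ci,
                       n_pos=len(pos), n_neg=len(neg), v_pos=v_pos, v_neg=v_neg)


def delong_test(risks_a, risks_b, labels: np.ndarray) -> tuple[float, float]:
    """Paired DeLong test for two risk vectors scored on the same labels.

    Returns (z statistic, two-sided p-value).
    """
    ra = auroc_delong(risks_a, labels)
    rb = auroc_delong(risks_b, labels)
    m, n = ra.n_pos, ra.n_neg
    cov = 0.0
    if m > 1:
        cov += np.cov(ra.v_pos, rb.v_pos, ddof=1)[0, 1] / m
    if n > 1:
        cov += np.cov(ra.v_neg, rb.v_neg, ddof=1)[0, 1] / n
    var_diff = ra.variance + rb.variance - 2 * cov
    if var_diff <= 0:
        return 0.0, 1.0
    z = (ra.auc - rb.auc) / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)
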