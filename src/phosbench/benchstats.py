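"""Benchmark statistics for spike-in quantification comparisons.

Covers the statistics used to rank quantification methods on designs with
known ground truth:

* the SAM (significance analysis of microarrays) moderated t-statistic
  d = r / (s + s0), its automatic background-variance offset s0, and the
  permutation-based delta / FDR calibration;
* ROC curves from d-scores against known spike-in labels;
* the squared-bias + variance decomposition of the mean squared error;
* the ratio-decompression slope (OLS of one method's extreme log2 ratios
  against a compressed reference);
* a least-squares estimator of the co-isolation contamination fraction
  from reporter-channel profiles.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from sklearn import metrics as _skmetrics

__all__ = [
    "SamResult",
    "RocCurve",
    "ErrorDecomposition",
    "ContaminationEstimate",
    "sam_statistic",
    "estimate_s0",
    "sam_significance",
    "roc_curve",
    "error_decomposition",
    "decompression_slope",
    "estimate_contamination_fraction",
]


# ---------------------------------------------------------------------------
# SAM d-statistic
# ---------------------------------------------------------------------------

def _group_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise count, mean and sum of squared deviations, NaN-aware."""
    present = ~np.isnan(x)
    n = present.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(present, x, np.nan), axis=1)
        ss = np.nansum((x - mean[:, None]) ** 2, axis=1)
    return n, mean, ss


def sam_statistic(
    group1: np.ndarray,
    group2: np.ndarray,
    design: str = "unpaired",
    s0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature SAM statistic d = r / (s_i + s0) and denominator s_i.

    Unpaired: r is the difference of group means and s_i the pooled-variance
    standard error; paired: r is the mean of within-replicate differences
    (group1 - group2) and s_i its standard error.  With ``s0 = 0`` the
    statistic is the classical t-statistic.  Features with fewer than two
    usable observations per group (or pairs) get NaN rather than raising.
    """
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    g1 = np.atleast_2d(np.asarray(group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(group2, dtype=float))
    if g1.shape[0] != g2.shape[0]:
        raise ValueError("groups must cover the same features")

    if design == "paired":
        if g1.shape != g2.shape:
            raise ValueError("paired design needs equal replicate counts")
        diffs = g1 - g2
        n, mean, ss = _group_stats(diffs)
        with np.errstate(invalid="ignore", divide="ignore"):
            s_i = np.sqrt(ss / (n - 1) / n)
        r = mean
        ok = n >= 2
    elif design == "unpaired":
        n1, m1, ss1 = _group_stats(g1)
        n2, m2, ss2 = _group_stats(g2)
        with np.errstate(invalid="ignore", divide="ignore"):
            pooled = (ss1 + ss2) / (n1 + n2 - 2)
            s_i = np.sqrt((1.0 / n1 + 1.0 / n2) * pooled)
        r = m1 - m2
        ok = (n1 >= 2) & (n2 >= 2)
    else:
        raise ValueError(f"design must be 'paired' or 'unpaired', got {design!r}")

    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(ok & (s_i + s0 > 0), r / (s_i + s0), np.nan)
    s_i = np.where(ok, s_i, np.nan)
    return d, s_i


def estimate_s0(numerators: np.ndarray, denominators: np.ndarray) -> float:
    """Automatic SAM background-variance offset s0.

    Candidates are 0 plus the percentiles {0, 5, ..., 100} of the
    denominators s_i.  For each candidate the features are split into 100
    quantile bins of s_i; the candidate minimizing the coefficient of
    variation of the per-bin median absolute deviations of d is returned
    (ties broken toward the smallest candidate).  The offset stabilizes
    the spread of d across the variance range, preventing low-variance
    features from dominating the significant list.
    """
    r = np.asarray(numerators, dtype=float)
    s = np.asarray(denominators, dtype=float)
    ok = np.isfinite(r) & np.isfinite(s)
    r, s = r[ok], s[ok]
    n = r.size
    if n == 0 or np.all(s == 0):
        warnings.warn("all denominators zero or empty; s0 = 0", stacklevel=2)
        return 0.0
    if n < 100:
        warnings.warn(f"s0 estimation on only {n} features is unstable", stacklevel=2)

    candidates = np.unique(np.concatenate(
        [[0.0], np.percentile(s, np.arange(0, 101, 5))]
    ))
    order = np.argsort(s, kind="mergesort")
    n_bins = min(100, n)
    bins = np.array_split(order, n_bins)

    best_s0, best_cv = 0.0, math.inf
    for alpha in candidates:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = r / (s + alpha)
        mads = np.array([
            np.median(np.abs(d[b] - np.median(d[b]))) for b in bins if b.size
        ])
        mean_mad = mads.mean()
        cv = mads.std() / mean_mad if mean_mad > 0 else math.inf
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(alpha)
    return best_s0


# ---------------------------------------------------------------------------
# SAM permutation significance
# ---------------------------------------------------------------------------

@dataclass
class SamResult:
    """Outcome of SAM permutation testing.

    ``significant`` holds +1 (up), -1 (down) or 0 per feature, aligned
    with the input feature order; ``expected_d`` are the permutation-mean
    order statistics aligned with ascending observed d.
    """

    d: np.ndarray
    s_i: np.ndarray
    s0: float
    expected_d: np.ndarray
    delta: float
    significant: np.ndarray
    estimated_fdr: float
    n_permutations: int
    seed: int
    pi0: float
    cut_up: float
    cut_down: float
    exhaustive: bool = False

    @property
    def n_called(self) -> int:
        return int(np.sum(self.significant != 0))


def _unpaired_permutations(n1: int, n2: int, n_perm: int, rng) -> tuple[list, bool]:
    total = math.comb(n1 + n2, n1)
    if total <= n_perm:
        combos = [np.array(c) for c in itertools.combinations(range(n1 + n2), n1)]
        return combos, True
    picks = []
    for _ in range(n_perm):
        picks.append(rng.permutation(n1 + n2)[:n1])
    return picks, False


def _paired_signflips(n: int, n_perm: int, rng) -> tuple[np.ndarray, bool]:
    if 2**n <= n_perm:
        flips = np.array(
            [[1 if (m >> j) & 1 == 0 else -1 for j in range(n)] for m in range(2**n)]
        )
        return flips, True
    return rng.choice([-1.0, 1.0], size=(n_perm, n)), False


def sam_significance(
    group1: np.ndarray,
    group2: np.ndarray,
    design: str = "unpaired",
    s0: float | str = "auto",
    delta: float | str = "auto",
    target_fdr: float = 0.20,
    n_permutations: int = 200,
    seed: int = 123,
) -> SamResult:
    """SAM significance calls with permutation-calibrated delta and FDR.

    Permutation-expected order statistics of d are built by permuting
    group labels (paired design: sign flips of the differences) with a
    fixed seed.  A feature is called when its ordered d deviates from the
    expected value by at least ``delta`` on the matching tail; with
    ``delta="auto"`` the smallest delta whose median-permutation FDR is
    <= ``target_fdr`` is chosen.  The FDR estimate is

        pi0 * median permuted call count / observed call count,

    with pi0 estimated from the fraction of observed d inside the central
    50% of the permuted d distribution.  If more permutations are
    requested than distinct arrangements exist, the exhaustive set is used
    and flagged on the result.
    """
    if not 0.0 < target_fdr < 1.0:
        raise ValueError("target_fdr must be in (0, 1)")
    if n_permutations < 25:
        raise ValueError("need at least 25 permutations")
    g1 = np.atleast_2d(np.asarray(group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(group2, dtype=float))

    d_all, s_all = sam_statistic(g1, g2, design=design, s0=0.0)
    if s0 == "auto":
        with np.errstate(invalid="ignore", divide="ignore"):
            r_all = d_all * s_all
        s0_val = estimate_s0(r_all, s_all)
    else:
        s0_val = float(s0)
    d_all, s_all = sam_statistic(g1, g2, design=design, s0=s0_val)

    valid = np.isfinite(d_all)
    d = d_all[valid]
    n = d.size
    if n == 0:
        raise ValueError("no feature has a computable d-statistic")
    rng = np.random.default_rng(seed)

    # permuted d matrices, each row one permutation, sorted ascending
    if design == "paired":
        diffs = (g1 - g2)[valid]
        nrep = diffs.shape[1]
        flips, exhaustive = _paired_signflips(nrep, n_permutations, rng)
        perm_sorted = np.empty((len(flips), n))
        for b, fl in enumerate(flips):
            dp, _ = sam_statistic(diffs * fl, np.zeros_like(diffs),
                                  design="paired", s0=s0_val)
            perm_sorted[b] = np.sort(dp)
    else:
        pooled = np.hstack([g1[valid], g2[valid]])
        n1, n2 = g1.shape[1], g2.shape[1]
        picks, exhaustive = _unpaired_permutations(n1, n2, n_permutations, rng)
        perm_sorted = np.empty((len(picks), n))
        all_idx = np.arange(n1 + n2)
        for b, pick in enumerate(picks):
            rest = np.setdiff1d(all_idx, pick, assume_unique=True)
            dp, _ = sam_statistic(pooled[:, pick], pooled[:, rest],
                                  design="unpaired", s0=s0_val)
            perm_sorted[b] = np.sort(dp)
    # paired sign-flip of all +1 (or the identity permutation) is included
    # by construction when exhaustive; otherwise random — both standard.

    n_perm_used = perm_sorted.shape[0]
    expected_d = perm_sorted.mean(axis=0)

    order = np.argsort(d, kind="mergesort")
    d_sorted = d[order]

    # pi0 from the central 50% of the permuted distribution
    q25, q75 = np.percentile(perm_sorted, [25, 75])
    pi0 = min(1.0, np.mean((d >= q25) & (d <= q75)) / 0.5)

    diffs_sorted = d_sorted - expected_d
    up_mask = expected_d >= 0
    down_mask = expected_d <= 0

    def cuts_for(delta_val: float) -> tuple[float, float]:
        up = up_mask & (diffs_sorted >= delta_val)
        cut_up = d_sorted[up].min() if up.any() else math.inf
        down = down_mask & (-diffs_sorted >= delta_val)
        cut_down = d_sorted[down].max() if down.any() else -math.inf
        return cut_up, cut_down

    def evaluate(delta_val: float) -> tuple[float, float, float, int]:
        cut_up, cut_down = cuts_for(delta_val)
        called = (d >= cut_up) | (d <= cut_down)
        n_called = int(called.sum())
        if n_called == 0:
            return 0.0, cut_up, cut_down, 0
        # per-permutation counts beyond the cuts
        counts = np.array([
            row.size - np.searchsorted(row, cut_up, side="left")
            + np.searchsorted(row, cut_down, side="right")
            for row in perm_sorted
        ])
        fdr = min(1.0, pi0 * float(np.median(counts)) / n_called)
        return fdr, cut_up, cut_down, n_called

    if delta == "auto":
        candidates = np.unique(np.concatenate([[0.0], np.abs(diffs_sorted)]))
        chosen = None
        for cand in candidates:
            fdr, cut_up, cut_down, n_called = evaluate(cand)
            if fdr <= target_fdr:
                chosen = (float(cand), fdr, cut_up, cut_down)
                break
        if chosen is None:  # no calls at the largest delta -> FDR 0
            cand = float(candidates[-1] + 1.0)
            fdr, cut_up, cut_down, _ = evaluate(cand)
            chosen = (cand, fdr, cut_up, cut_down)
        delta_val, fdr, cut_up, cut_down = chosen
    else:
        delta_val = float(delta)
        fdr, cut_up, cut_down, _ = evaluate(delta_val)

    significant = np.zeros(d_all.shape, dtype=int)
    significant[valid] = np.where(d >= cut_up, 1, np.where(d <= cut_down, -1, 0))

    return SamResult(
        d=d_all, s_i=s_all, s0=s0_val, expected_d=expected_d, delta=delta_val,
        significant=significant, estimated_fdr=fdr, n_permutations=n_perm_used,
        seed=seed, pi0=pi0, cut_up=cut_up, cut_down=cut_down,
        exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    """ROC curve points and trapezoid AUC (ties form diagonal segments)."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    positive_count: int
    negative_count: int
    n_missing: int = 0


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve of scores against binary labels (higher score = positive).

    Missing scores are excluded (and counted); thresholds sweep descending
    unique scores with ties handled as single blocks, so tied scores
    produce diagonal segments and the AUC equals pairwise concordance with
    ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    ok = np.isfinite(scores)
    n_missing = int((~ok).sum())
    scores, labels = scores[ok], labels[ok]
    pos, neg = int(labels.sum()), int((~labels).sum())
    if pos == 0 or neg == 0:
        raise ValueError("ROC needs both a positive and a negative class")
    fpr, tpr, _ = _skmetrics.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc,
                    positive_count=pos, negative_count=neg, n_missing=n_missing)


# ---------------------------------------------------------------------------
# MSE decomposition
# ---------------------------------------------------------------------------

@dataclass
class ErrorDecomposition:
    """MSE split into squared bias ("positive bias") and population variance."""

    bias: float
    positive_bias: float
    variance: float
    mse: float
    n: int
    truth: float


def error_decomposition(estimates: np.ndarray, truth: float) -> ErrorDecomposition:
    """Decompose the mean squared error of estimates around a known truth.

    mse = (mean - truth)^2 + population variance, which equals the mean
    squared deviation from the truth exactly.
    """
    x = np.asarray(estimates, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite estimates")
    bias = float(x.mean() - truth)
    variance = float(x.var(ddof=0))
    return ErrorDecomposition(
        bias=bias, positive_bias=bias**2, variance=variance,
        mse=bias**2 + variance, n=int(x.size), truth=float(truth),
    )


# ---------------------------------------------------------------------------
# Decompression slope
# ---------------------------------------------------------------------------

def decompression_slope(
    reference_log2: np.ndarray,
    other_log2: np.ndarray,
    tail_fraction: float = 0.05,
) -> tuple[float, float, int]:
    """Slope of one method's extreme log2 ratios against a reference.

    Features in the top and bottom ``tail_fraction`` of the *reference*
    ratios are selected; ordinary least squares with intercept of
    ``other ~ reference`` on their union yields the decompression factor
    (> 1: the other method's ratios are more extreme than the compressed
    reference).  Returns (slope, intercept, n_used).
    """
    if not 0.0 < tail_fraction <= 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5]")
    ref = np.asarray(reference_log2, dtype=float)
    oth = np.asarray(other_log2, dtype=float)
    if ref.shape != oth.shape:
        raise ValueError("ratio vectors must align on common features")
    ok = np.isfinite(ref) & np.isfinite(oth)
    ref, oth = ref[ok], oth[ok]
    n = ref.size
    n_tail = int(np.ceil(tail_fraction * n))
    if n_tail < 10:
        raise ValueError(
            f"only {n_tail} features per tail from {n} valid pairs; need >= 10"
        )
    order = np.argsort(ref, kind="mergesort")
    sel = np.concatenate([order[:n_tail], order[-n_tail:]])
    x, y = ref[sel], oth[sel]
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    slope = float(np.sum((x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    return slope, intercept, int(sel.size)


# ---------------------------------------------------------------------------
# Contamination fraction
# ---------------------------------------------------------------------------

class ContaminationEstimate(NamedTuple):
    f: float
    residual_norm: float


def estimate_contamination_fraction(
    observed_profile: np.ndarray,
    true_profile: np.ndarray,
    background_profile: np.ndarray,
) -> ContaminationEstimate:
    """Fraction of reporter signal attributable to co-isolated background.

    Solves observed = (1 - f) * true + f * background in least squares:
    f = sum((o - t)(g - t)) / sum((g - t)^2), clipped to [0, 1].  Profiles
    are normalized to sum 1 internally.
    """
    o = np.asarray(observed_profile, dtype=float)
    t = np.asarray(true_profile, dtype=float)
    g = np.asarray(background_profile, dtype=float)
    if not (o.shape == t.shape == g.shape):
        raise ValueError("profiles must have equal length")
    o, t, g = o / o.sum(), t / t.sum(), g / g.sum()
    denom = float(np.sum((g - t) ** 2))
    if denom == 0.0:
        raise ValueError("true and background profiles coincide; f unidentifiable")
    f = float(np.sum((o - t) * (g - t)) / denom)
    f = min(1.0, max(0.0, f))
    resid = float(np.linalg.norm(o - ((1 - f) * t + f * g)))
    return ContaminationEstimate(f=f, residual_norm=resid)
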