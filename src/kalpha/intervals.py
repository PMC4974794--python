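"""Confidence intervals for agreement coefficients.

Three constructions:

* :func:`asymptotic_ci` — the normal-theory interval ``K +/- z_{1-a/2} se(K)``
  for Fleiss' K.  Valid only near the null K = 0; kept because it is what
  most software reports.
* :func:`subject_bootstrap` — the standard percentile bootstrap for either
  coefficient: each replicate redraws N subjects with replacement, keeping
  every rater's value within a drawn subject, and re-estimates.  This
  preserves the within-subject dependence between raters.
* :func:`coincidence_bootstrap` — Krippendorff's original algorithm for
  alpha, included for comparison: the expected disagreement is frozen at its
  full-data value, and each replicate redraws individual pairable-value
  coincidences from the coincidence-matrix distribution (ignoring that pairs
  within a subject are dependent), recomputing only the observed
  disagreement.  Because the within-subject dependence is dropped, its
  intervals are too narrow and their coverage falls well short of the
  nominal level.

Bootstrap replicates on resampled data in which a single category survives
are degenerate (0/0) and evaluate to 1.0 by the package convention; they are
kept (the replicate count stays at B) and counted in
:class:`BootstrapDistribution.n_degenerate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import (
    TOL,
    DistanceMetric,
    coincidence_matrix,
    delta_matrix,
    fleiss_k,
    krippendorff_alpha,
    metric_for,
)
from .exceptions import EstimationError, ValidationError
from .ratings import CategoryCounts, RatingTable, count_matrix


@dataclass(frozen=True)
class CISettings:
    """Confidence-interval settings: two-sided level, replicate count, seed."""

    level: float = 0.95
    n_boot: int = 1000
    seed: object = None  # anything numpy.random.default_rng accepts
    retry_cap: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValidationError("confidence level must be in (0, 1)")
        if self.n_boot < 1:
            raise ValidationError("at least one bootstrap replicate is required")


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    method: str  # "asymptotic" | "subject_bootstrap" | "coincidence_bootstrap"
    level: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValidationError("confidence interval bounds are out of order")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class BootstrapDistribution:
    """Sorted vector of replicate estimates from which percentile CIs are read."""

    estimates: np.ndarray  # sorted ascending, length B
    n_degenerate: int = 0

    @property
    def n_boot(self) -> int:
        return len(self.estimates)


def asymptotic_ci(estimate: float, se: float, settings: CISettings) -> ConfidenceInterval:
    """Normal-theory interval ``estimate +/- z_{1-alpha/2} * se``, not truncated to [-1, 1]."""
    if se < 0:
        raise ValidationError("standard error must be non-negative")
    z = stats.norm.ppf(1.0 - (1.0 - settings.level) / 2.0)
    return ConfidenceInterval(
        lower=float(estimate - z * se),
        upper=float(estimate + z * se),
        method="asymptotic",
        level=settings.level,
    )


def percentile_interval(sorted_estimates: np.ndarray, level: float) -> tuple[float, float]:
    """Percentile CI endpoints as 1-based order statistics at ceil(B*a/2), ceil(B*(1-a/2))."""
    b = len(sorted_estimates)
    alpha = 1.0 - level
    # ceil with a guard so that B*alpha/2 landing on an integer (up to float
    # error, e.g. 1000 * 0.05/2) maps to that order statistic, not the next
    lo = min(max(math.ceil(b * alpha / 2.0 - 1e-9), 1), b)
    hi = min(max(math.ceil(b * (1.0 - alpha / 2.0) - 1e-9), 1), b)
    return float(sorted_estimates[lo - 1]), float(sorted_estimates[hi - 1])


def hypothesis_flags(ci: ConfidenceInterval, thresholds) -> dict[str, bool]:
    """For each threshold t, is the CI's lower bound above t (one-sided conclusion)?"""
    return {f"above_{t:g}": bool(ci.lower > t) for t in thresholds}


# ---------------------------------------------------------------------------
# Vectorized replicate kernels
# ---------------------------------------------------------------------------
# A resample of N subjects with replacement is represented by its multiplicity
# vector w (length N, sum N), so B replicates form a B x N weight matrix and
# every per-replicate sufficient statistic is one matrix product away.

def _resample_weights(rng: np.random.Generator, n_subjects: int, size: int) -> np.ndarray:
    return rng.multinomial(n_subjects, np.full(n_subjects, 1.0 / n_subjects), size=size)


def _fleiss_replicates(
    weights: np.ndarray, counts: CategoryCounts
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fleiss' K for each weighted resample.

    Returns (values, degenerate_mask, invalid_mask); invalid replicates have
    fewer than two complete-case subjects and carry NaN.
    """
    n = counts.n_raters
    complete = (counts.row_totals == n).astype(float)
    p_i = np.where(
        complete > 0,
        (np.square(counts.counts).sum(axis=1) - n) / (n * (n - 1)),
        0.0,
    )
    feats = np.concatenate(
        [complete[:, None], (p_i * complete)[:, None], counts.counts * complete[:, None]],
        axis=1,
    )
    totals = weights @ feats  # B x (k + 2)
    n_ret = totals[:, 0]
    invalid = n_ret < 2
    with np.errstate(divide="ignore", invalid="ignore"):
        p_bar = totals[:, 1] / n_ret
        p_j = totals[:, 2:] / (n_ret * n)[:, None]
        p_e = np.square(p_j).sum(axis=1)
        values = (p_bar - p_e) / (1.0 - p_e)
    degenerate = (1.0 - p_e <= TOL) & ~invalid
    values = np.where(degenerate, 1.0, values)
    values = np.where(invalid, np.nan, values)
    return values, degenerate, invalid


def _alpha_replicates(
    weights: np.ndarray, counts: CategoryCounts, kind: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Krippendorff's alpha for each weighted resample of subjects."""
    k = counts.k
    m = counts.row_totals
    keep = m >= 2
    nc = counts.counts.astype(float) * keep[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        w_u = np.where(keep, 1.0 / np.maximum(m - 1.0, 1.0), 0.0)
    # per-subject coincidence contribution, flattened to N x k^2
    o_u = np.einsum("u,uc,ud->ucd", w_u, nc, nc)
    diag = np.arange(k)
    o_u[:, diag, diag] -= w_u[:, None] * nc
    o_b = (weights @ o_u.reshape(len(m), k * k)).reshape(-1, k, k)

    marg = o_b.sum(axis=2)          # B x k
    n_tot = marg.sum(axis=1)        # B
    invalid = n_tot < 2.0 - 1e-9
    if kind == "nominal":
        delta = 1.0 - np.eye(k)
        d_o_num = (o_b * delta).sum(axis=(1, 2))
        d_e_num = (np.einsum("bc,bd,cd->b", marg, marg, delta))
    else:
        mid = np.cumsum(marg, axis=1) - marg / 2.0
        delta_b = np.square(mid[:, None, :] - mid[:, :, None])  # B x k x k
        d_o_num = (o_b * delta_b).sum(axis=(1, 2))
        d_e_num = (marg[:, :, None] * marg[:, None, :] * delta_b).sum(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d_o = d_o_num / n_tot
        d_e = d_e_num / (n_tot * (n_tot - 1.0))
        values = 1.0 - d_o / d_e
    degenerate = (d_e <= TOL * np.maximum(1.0, n_tot**2)) & ~invalid
    values = np.where(degenerate, 1.0, values)
    values = np.where(invalid, np.nan, values)
    return values, degenerate, invalid


def _bootstrap(
    counts: CategoryCounts,
    kernel,
    settings: CISettings,
    method: str,
) -> tuple[BootstrapDistribution, ConfidenceInterval]:
    rng = np.random.default_rng(settings.seed)
    n_subj = counts.n_subjects
    weights = _resample_weights(rng, n_subj, settings.n_boot)
    values, degenerate, invalid = kernel(weights, counts)
    tries = 0
    while invalid.any():
        if tries >= settings.retry_cap:
            raise EstimationError(
                f"{int(invalid.sum())} bootstrap replicates remained inestimable "
                f"after {settings.retry_cap} redraws (too few estimable subjects)"
            )
        idx = np.flatnonzero(invalid)
        redraw = _resample_weights(rng, n_subj, len(idx))
        v, d, bad = kernel(redraw, counts)
        values[idx], degenerate[idx] = v, d
        invalid[idx] = bad
        tries += 1
    order = np.sort(values)
    lower, upper = percentile_interval(order, settings.level)
    dist = BootstrapDistribution(estimates=order, n_degenerate=int(degenerate.sum()))
    ci = ConfidenceInterval(lower=lower, upper=upper, method=method, level=settings.level)
    return dist, ci


def subject_bootstrap(
    ratings: RatingTable,
    estimator: str,
    metric: DistanceMetric | None = None,
    settings: CISettings | None = None,
) -> tuple[BootstrapDistribution, ConfidenceInterval]:
    """Standard percentile bootstrap: resample subjects, re-estimate, take percentiles.

    ``estimator`` is ``"fleiss_k"`` or ``"krippendorff_alpha"``.  Each
    replicate draws subjects with replacement, keeping all raters' values
    within a drawn subject.  For Fleiss' K the complete-case deletion is
    applied first, so replicates resample the N_retained complete
    observations (the dataset K actually sees); for alpha all N subjects are
    resampled and units with fewer than two ratings simply contribute
    nothing.  Replicates whose resample is inestimable are redrawn, up to
    ``settings.retry_cap`` passes.  The seed fully determines the output.
    """
    settings = settings or CISettings()
    counts = count_matrix(ratings)
    if estimator == "fleiss_k":
        fleiss_k(counts)  # validate estimability before resampling
        # Complete-case analysis happens before the bootstrap: incomplete
        # subjects are deleted from the dataset, and the N_retained remaining
        # observations are what each replicate resamples.
        keep = counts.row_totals == counts.n_raters
        counts = CategoryCounts(counts=counts.counts[keep], n_raters=counts.n_raters)
        kernel = _fleiss_replicates
    elif estimator == "krippendorff_alpha":
        kind = (metric or metric_for(ratings.scale)).kind

        def kernel(w, c):
            return _alpha_replicates(w, c, kind)

    else:
        raise ValidationError(f"unknown estimator {estimator!r}")
    return _bootstrap(counts, kernel, settings, method="subject_bootstrap")


def coincidence_bootstrap(
    ratings: RatingTable,
    metric: DistanceMetric | None = None,
    settings: CISettings | None = None,
) -> tuple[BootstrapDistribution, ConfidenceInterval]:
    """Krippendorff's coincidence-matrix bootstrap for alpha.

    The expected disagreement D_e (and, for the ordinal metric, the distance
    matrix) is fixed at its full-data value.  Each replicate draws
    ``M = sum_u m_u (m_u - 1) / 2`` pairable-value coincidences — one per
    distinct within-subject pair, so subjects with more ratings carry
    proportionally more weight — from the cell distribution ``o_cc' / n..``
    of the coincidence matrix, and only the observed disagreement is
    recomputed: ``alpha_b = 1 - D_o,b / D_e``.
    """
    settings = settings or CISettings()
    metric = metric or metric_for(ratings.scale)
    counts = count_matrix(ratings)
    coinc = coincidence_matrix(counts)
    marg = coinc.marginals
    n_tot = coinc.grand_total
    delta = metric.matrix(marg)
    d_e = float((np.outer(marg, marg) * delta).sum()) / (n_tot * (n_tot - 1.0))
    m = counts.row_totals
    m = m[m >= 2]
    n_pairs = int((m * (m - 1) // 2).sum())

    rng = np.random.default_rng(settings.seed)
    if d_e <= TOL * max(1.0, n_tot**2):
        values = np.ones(settings.n_boot)
        n_degen = settings.n_boot
    else:
        probs = np.maximum(coinc.o.ravel(), 0.0)
        probs = probs / probs.sum()
        draws = rng.multinomial(n_pairs, probs, size=settings.n_boot)
        d_o_b = (draws @ delta.ravel()) / n_pairs
        values = 1.0 - d_o_b / d_e
        n_degen = 0
    order = np.sort(values)
    lower, upper = percentile_interval(order, settings.level)
    dist = BootstrapDistribution(estimates=order, n_degenerate=n_degen)
    ci = ConfidenceInterval(
        lower=lower, upper=upper, method="coincidence_bootstrap", level=settings.level
    )
    return dist, ci
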