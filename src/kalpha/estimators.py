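"""Chance-corrected agreement coefficients for multi-rater categorical data.

Two coefficients are implemented:

* **Fleiss' K** — observed agreement corrected for the agreement expected by
  chance, ``K = (P_bar - P_e) / (1 - P_e)``.  It requires complete data:
  every subject with fewer than ``n`` ratings is dropped (complete-case
  analysis) before estimation.  The corrected large-sample standard error of
  Fleiss, Nee and Landis is provided; it is valid only for testing the null
  hypothesis K = 0.
* **Krippendorff's alpha** — observed disagreement corrected for the
  disagreement expected by chance, ``alpha = 1 - D_o / D_e``, computed from
  the coincidence matrix of pairable values.  Subjects need at least two
  ratings to contribute, so alpha tolerates missing cells, and the chance
  term uses the actual number of pairable values ``n..`` rather than an
  infinite-sample limit.  Nominal and ordinal distance metrics are supported.

Both coefficients live on [-1, 1]: 1 is perfect agreement, 0 is agreement at
chance level, negative values indicate systematic disagreement.  When a
single category is used everywhere both coefficients are 0/0; by convention
the package returns 1.0 with ``degenerate_flag`` set (agreement is trivially
perfect) and emits a :class:`~kalpha.exceptions.DegenerateDataWarning`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exceptions import DegenerateDataWarning, EstimationError, ValidationError
from .ratings import CategoryCounts, RatingTable, count_matrix

#: Relative tolerance for degeneracy / invariant checks.
TOL = 1e-10


# ---------------------------------------------------------------------------
# Fleiss' K
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FleissComponents:
    """Intermediate quantities behind a Fleiss' K estimate."""

    per_subject_agreement: np.ndarray  # P_i for each retained subject
    mean_agreement: float              # P_bar
    marginal_props: np.ndarray         # p_j
    chance_agreement: float            # P_e = sum p_j^2
    n_retained: int                    # complete-case subjects used


@dataclass(frozen=True)
class AgreementEstimate:
    """A point estimate of an agreement coefficient.

    ``components`` is a :class:`FleissComponents` for Fleiss' K and the pair
    ``(D_o, D_e)`` of observed/expected disagreement for Krippendorff's
    alpha.  ``degenerate_flag`` marks estimates defined only by convention
    (single used category -> value 1.0).
    """

    value: float
    method: str  # "fleiss_k" | "krippendorff_alpha"
    components: object
    n_subjects_used: int
    degenerate_flag: bool = False


def fleiss_k(counts: CategoryCounts) -> AgreementEstimate:
    """Fleiss' K on the complete cases of a count matrix.

    Subjects with fewer than ``n`` ratings are deleted.  On the retained
    subjects, with ``n`` raters and tallies ``n_ij``::

        P_i   = (sum_j n_ij^2 - n) / (n (n - 1))
        P_bar = mean_i P_i
        p_j   = sum_i n_ij / (N_retained * n)
        P_e   = sum_j p_j^2
        K     = (P_bar - P_e) / (1 - P_e)
    """
    n = counts.n_raters
    complete = counts.row_totals == n
    retained = counts.counts[complete]
    n_ret = retained.shape[0]
    if n_ret < 2:
        raise EstimationError(
            f"Fleiss' K needs at least 2 complete-case subjects, got {n_ret} "
            f"(of {counts.n_subjects})",
            n_subjects_used=n_ret,
        )
    p_i = (np.square(retained).sum(axis=1) - n) / (n * (n - 1))
    p_bar = float(p_i.mean())
    p_j = retained.sum(axis=0) / (n_ret * n)
    p_e = float(np.square(p_j).sum())
    if 1.0 - p_e <= TOL:
        warnings.warn(
            "all retained ratings fall in a single category; Fleiss' K is 0/0 "
            "and set to 1.0 by convention",
            DegenerateDataWarning,
            stacklevel=2,
        )
        value, degenerate = 1.0, True
    else:
        value, degenerate = (p_bar - p_e) / (1.0 - p_e), False
    components = FleissComponents(
        per_subject_agreement=p_i,
        mean_agreement=p_bar,
        marginal_props=p_j,
        chance_agreement=p_e,
        n_retained=n_ret,
    )
    return AgreementEstimate(
        value=float(value),
        method="fleiss_k",
        components=components,
        n_subjects_used=n_ret,
        degenerate_flag=degenerate,
    )


def fleiss_k_se(counts: CategoryCounts) -> float:
    """Corrected large-sample standard error of Fleiss' K (Fleiss-Nee-Landis).

    With ``q_j = p_j (1 - p_j)``::

        se(K) = sqrt(2 / (N n (n-1))) * sqrt((sum_j q_j)^2 - sum_j q_j (1 - 2 p_j))
                / sum_j q_j

    Only appropriate for testing the hypothesis that the underlying
    coefficient is zero; off the null it underestimates the spread.
    """
    n = counts.n_raters
    complete = counts.row_totals == n
    retained = counts.counts[complete]
    n_ret = retained.shape[0]
    if n_ret < 2:
        raise EstimationError(
            f"Fleiss' K standard error needs at least 2 complete-case subjects, got {n_ret}",
            n_subjects_used=n_ret,
        )
    p_j = retained.sum(axis=0) / (n_ret * n)
    q_j = p_j * (1.0 - p_j)
    s = float(q_j.sum())
    if s <= TOL:
        raise EstimationError(
            "standard error undefined: a single category is used everywhere",
            n_subjects_used=n_ret,
        )
    inner = s * s - float((q_j * (1.0 - 2.0 * p_j)).sum())
    return float(np.sqrt(2.0 / (n_ret * n * (n - 1))) * np.sqrt(inner) / s)


# ---------------------------------------------------------------------------
# Coincidence matrix and Krippendorff's alpha
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoincidenceMatrix:
    """k x k tally of pairable value coincidences — alpha's sufficient statistic.

    Each retained subject ``u`` (one with ``m_u >= 2`` ratings) contributes
    ``n_uc * n_uc' / (m_u - 1)`` to the off-diagonal cell (c, c') and
    ``n_uc (n_uc - 1) / (m_u - 1)`` to the diagonal, so its ``m_u`` pairable
    values are counted exactly once in the grand total ``n..``.
    """

    o: np.ndarray
    excluded_units: int

    @property
    def marginals(self) -> np.ndarray:
        return self.o.sum(axis=1)

    @property
    def grand_total(self) -> float:
        return float(self.o.sum())


def coincidence_matrix(counts: CategoryCounts) -> CoincidenceMatrix:
    """Build the coincidence matrix, excluding subjects with fewer than two ratings."""
    m = counts.row_totals
    keep = m >= 2
    excluded = int((~keep).sum())
    if not keep.any():
        raise EstimationError(
            "Krippendorff's alpha needs at least one subject with >= 2 ratings",
            n_subjects_used=0,
        )
    nc = counts.counts[keep].astype(float)
    w = 1.0 / (m[keep] - 1.0)
    o = np.einsum("u,uc,ud->cd", w, nc, nc)
    o[np.diag_indices_from(o)] -= (w[:, None] * nc).sum(axis=0)
    return CoincidenceMatrix(o=o, excluded_units=excluded)


@dataclass(frozen=True)
class DistanceMetric:
    """A squared-difference function between categories.

    ``kind`` is ``"nominal"`` (0/1 mismatch) or ``"ordinal"`` (Krippendorff's
    cumulative-marginal metric, computed from the retained-data marginals of
    the coincidence matrix, not from user-supplied weights).
    """

    kind: str
    delta: Callable[[int, int, np.ndarray], float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("nominal", "ordinal"):
            raise ValidationError(f"unknown metric kind {self.kind!r}")

    def matrix(self, marginals: np.ndarray) -> np.ndarray:
        """The full k x k distance matrix for the given marginals."""
        return delta_matrix(self.kind, np.asarray(marginals, dtype=float))


NOMINAL = DistanceMetric(kind="nominal")
ORDINAL = DistanceMetric(kind="ordinal")


def metric_for(scale: str) -> DistanceMetric:
    return ORDINAL if scale == "ordinal" else NOMINAL


def delta_matrix(kind: str, marginals: np.ndarray) -> np.ndarray:
    """Distance matrix delta(c, c') for all category pairs.

    Nominal: ``1 - I(c == c')``.  Ordinal: with cumulative marginals
    ``S_c = sum_{g<=c} n_g`` and midpoints ``L_c = S_c - n_c / 2``,
    ``delta(c, c') = (L_c' - L_c)^2`` — the squared number of ratings lying
    between the two categories, counting half of each endpoint's marginal.
    """
    k = len(marginals)
    if kind == "nominal":
        return 1.0 - np.eye(k)
    mid = np.cumsum(marginals) - marginals / 2.0
    return np.square(mid[None, :] - mid[:, None])


def ordinal_delta(c: int, c_prime: int, marginals) -> float:
    """Ordinal distance between 1-based category codes ``c`` and ``c_prime``:
    ``(sum_{g=c}^{c'} n_g - (n_c + n_c') / 2)^2``."""
    marginals = np.asarray(marginals, dtype=float)
    lo, hi = sorted((c, c_prime))
    return float(
        np.square(marginals[lo - 1 : hi].sum() - (marginals[lo - 1] + marginals[hi - 1]) / 2.0)
    )


def krippendorff_alpha(
    coinc: CoincidenceMatrix, metric: DistanceMetric = NOMINAL
) -> AgreementEstimate:
    """Krippendorff's alpha from a coincidence matrix.

    ``D_o = sum_cc' o_cc' delta(c,c') / n..`` and
    ``D_e = sum_cc' n_c n_c' delta(c,c') / (n.. (n.. - 1))`` with the actual
    pairable-value total ``n..``; ``alpha = 1 - D_o / D_e``.
    """
    n_tot = coinc.grand_total
    if n_tot < 2:
        raise EstimationError(
            "Krippendorff's alpha needs at least 2 pairable values", n_subjects_used=0
        )
    marg = coinc.marginals
    delta = metric.matrix(marg)
    d_o = float((coinc.o * delta).sum()) / n_tot
    d_e = float((np.outer(marg, marg) * delta).sum()) / (n_tot * (n_tot - 1.0))
    if d_e <= TOL:
        warnings.warn(
            "all pairable ratings fall in a single category; alpha is 0/0 and "
            "set to 1.0 by convention",
            DegenerateDataWarning,
            stacklevel=2,
        )
        value, degenerate = 1.0, True
    else:
        value, degenerate = 1.0 - d_o / d_e, False
    return AgreementEstimate(
        value=float(value),
        method="krippendorff_alpha",
        components=(d_o, d_e),
        n_subjects_used=0,  # filled by the caller below
        degenerate_flag=degenerate,
    )


def alpha_from_ratings(
    ratings: RatingTable, metric: DistanceMetric | None = None
) -> AgreementEstimate:
    """Convenience wrapper: coincidence matrix + alpha straight from a table."""
    counts = count_matrix(ratings)
    coinc = coincidence_matrix(counts)
    if metric is None:
        metric = metric_for(ratings.scale)
    est = krippendorff_alpha(coinc, metric)
    used = int((counts.row_totals >= 2).sum())
    return AgreementEstimate(
        value=est.value,
        method=est.method,
        components=est.components,
        n_subjects_used=used,
        degenerate_flag=est.degenerate_flag,
    )


def fleiss_k_from_ratings(ratings: RatingTable) -> AgreementEstimate:
    """Convenience wrapper: count matrix + Fleiss' K straight from a table."""
    return fleiss_k(count_matrix(ratings))
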