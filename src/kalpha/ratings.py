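"""Wide-format categorical rating tables and their sufficient statistics.

The universal input is a subjects-by-raters matrix of category codes: row i
holds the ratings all raters gave to subject i.  Categories are encoded as
the integers ``1..k`` (the position in the user-supplied category order, which
also defines the ordinal rank); missing ratings are stored as ``0``.

Two sufficient statistics are derived from a :class:`RatingTable`:

* :class:`CategoryCounts` — the per-subject tallies ``n_ij`` (how many raters
  put subject *i* into category *j*), from which Fleiss' K is computed, and
* the coincidence matrix (see :mod:`kalpha.estimators`), from which
  Krippendorff's alpha is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

#: Integer code used for a missing rating inside ``RatingTable.values``.
MISSING: int = 0

_SCALES = ("nominal", "ordinal")


@dataclass(frozen=True)
class RatingTable:
    """An N x n matrix of category codes with explicit missing cells.

    Parameters
    ----------
    values
        Integer array of shape (N, n); entries are category codes in
        ``1..k`` or :data:`MISSING` (0).
    k
        Number of categories (>= 2).
    scale
        ``"nominal"`` or ``"ordinal"``; ordinal implies the codes are
        rank-ordered.
    categories
        Optional original labels; ``categories[c - 1]`` is the label of
        code ``c``.
    """

    values: np.ndarray
    k: int
    scale: str = "nominal"
    categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValidationError("ratings must form a 2-D subjects x raters matrix")
        if not np.issubdtype(values.dtype, np.integer):
            raise ValidationError("rating codes must be integers")
        n_subjects, n_raters = values.shape
        if n_subjects < 1:
            raise ValidationError("at least one subject is required")
        if n_raters < 2:
            raise ValidationError(f"at least 2 raters are required, got {n_raters}")
        if self.k < 2:
            raise ValidationError(f"at least 2 categories are required, got k={self.k}")
        if self.scale not in _SCALES:
            raise ValidationError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if values.min(initial=MISSING) < 0 or values.max(initial=MISSING) > self.k:
            bad = values[(values < 0) | (values > self.k)][0]
            raise ValidationError(
                f"category code {bad} outside the valid range 1..{self.k} (0 = missing)"
            )
        if self.categories is not None and len(self.categories) != self.k:
            raise ValidationError("categories must list exactly k labels")
        object.__setattr__(self, "values", values)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int((self.values == MISSING).sum())

    def label_of(self, code: int) -> str:
        if self.categories is not None:
            return str(self.categories[code - 1])
        return str(code)


@dataclass(frozen=True)
class CategoryCounts:
    """Per-subject category tallies ``n_ij`` — the sufficient statistic for Fleiss' K.

    ``counts[i, j]`` is the number of raters assigning subject ``i`` to
    category ``j + 1``; ``row_totals[i] = m_i`` is the number of ratings
    subject ``i`` received (``m_i = n`` iff the subject has no missing cell).
    """

    counts: np.ndarray
    n_raters: int
    row_totals: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be an N x k matrix")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_totals", counts.sum(axis=1))
        if self.row_totals.max(initial=0) > self.n_raters:
            raise ValidationError("a subject has more ratings than there are raters")

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def k(self) -> int:
        return self.counts.shape[1]


def encode_ratings(
    raw_table,
    category_order,
    missing_codes=(),
    scale: str = "nominal",
) -> RatingTable:
    """Map a table of labels onto integer codes ``1..k``.

    ``category_order`` defines both the code assignment (position + 1) and,
    for ordinal data, the rank order.  Cells whose (whitespace-stripped)
    label is in ``missing_codes`` become missing.

    Raises
    ------
    ValidationError
        If a non-missing label is not in ``category_order``, or the table has
        fewer than two raters or categories.
    """
    order = [str(c) for c in category_order]
    if len(order) < 2:
        raise ValidationError("category_order must list at least 2 categories")
    if len(set(order)) != len(order):
        raise ValidationError("category_order contains duplicate labels")
    missing = {str(m) for m in missing_codes}
    code_of = {label: c + 1 for c, label in enumerate(order)}

    raw = np.asarray(raw_table, dtype=object)
    if raw.ndim != 2:
        raise ValidationError("raw_table must be 2-D (rows = subjects, columns = raters)")
    n_subjects, n_raters = raw.shape
    if n_raters < 2:
        raise ValidationError(f"at least 2 raters are required, got {n_raters}")

    values = np.zeros((n_subjects, n_raters), dtype=np.int64)
    for i in range(n_subjects):
        for j in range(n_raters):
            cell = raw[i, j]
            label = "" if cell is None else str(cell).strip()
            if label in missing:
                continue
            try:
                values[i, j] = code_of[label]
            except KeyError:
                raise ValidationError(
                    f"unknown category label {label!r} at subject {i}, rater {j}; "
                    f"known categories: {order}"
                ) from None
    return RatingTable(values=values, k=len(order), scale=scale, categories=tuple(order))


def count_matrix(ratings: RatingTable) -> CategoryCounts:
    """Tally ``n_ij``, the number of raters giving category ``j`` to subject ``i``."""
    codes = np.arange(1, ratings.k + 1)
    counts = (ratings.values[:, :, None] == codes[None, None, :]).sum(axis=1)
    return CategoryCounts(counts=counts, n_raters=ratings.n_raters)
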