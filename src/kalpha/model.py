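"""Model / results objects for inter-rater reliability analyses.

:class:`InterRaterReliability` wraps a :class:`~kalpha.ratings.RatingTable`
(or a wide DataFrame of labels) and its :meth:`~InterRaterReliability.fit`
returns an :class:`AgreementResults` carrying the point estimates, their
confidence intervals, the bootstrap replicate distributions and a
``summary()`` table.

Example
-------
>>> import pandas as pd
>>> from kalpha import InterRaterReliability
>>> df = pd.DataFrame([[1, 1], [1, 1], [2, 2], [1, 2]])
>>> res = InterRaterReliability.from_dataframe(df).fit(seed=7)
>>> round(res.fleiss_k, 6), round(res.alpha, 6)
(0.466667, 0.533333)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import (
    AgreementEstimate,
    alpha_from_ratings,
    count_matrix,
    fleiss_k_from_ratings,
    fleiss_k_se,
    metric_for,
)
from .exceptions import ValidationError
from .intervals import (
    BootstrapDistribution,
    CISettings,
    ConfidenceInterval,
    asymptotic_ci,
    coincidence_bootstrap,
    hypothesis_flags,
    subject_bootstrap,
)
from .ratings import RatingTable, encode_ratings

_MEASURES = {"k": ("fleiss_k",), "alpha": ("krippendorff_alpha",),
             "both": ("fleiss_k", "krippendorff_alpha")}
_CI_CHOICES = ("asymptotic", "bootstrap", "both", "none")


class InterRaterReliability:
    """Chance-corrected inter-rater agreement model for categorical ratings.

    Parameters
    ----------
    ratings
        A :class:`~kalpha.ratings.RatingTable` (rows = subjects, columns =
        raters).
    """

    def __init__(self, ratings: RatingTable):
        self.ratings = ratings

    @classmethod
    def from_dataframe(
        cls,
        data,
        categories=None,
        missing_codes=("", "NA", "."),
        scale: str = "nominal",
    ) -> "InterRaterReliability":
        """Build the model from a wide table of labels (DataFrame, array or nested list).

        ``categories`` fixes the category order (required for ordinal data,
        where it defines the ranks); if omitted for nominal data the sorted
        distinct labels are used.
        """
        raw = np.asarray(pd.DataFrame(data), dtype=object)
        missing = {str(m) for m in missing_codes}
        if categories is None:
            if scale == "ordinal":
                raise ValidationError(
                    "ordinal data needs an explicit category order (categories=...)"
                )
            labels = {
                str(cell).strip()
                for cell in raw.ravel()
                if cell is not None and str(cell).strip() not in missing
            }
            try:
                categories = sorted(labels, key=float)
            except ValueError:
                categories = sorted(labels)
        return cls(encode_ratings(raw, categories, missing_codes, scale=scale))

    def fit(
        self,
        measures: str = "both",
        ci: str = "bootstrap",
        level: float = 0.95,
        n_boot: int = 1000,
        seed=None,
        include_coincidence_bootstrap: bool = False,
    ) -> "AgreementResults":
        """Estimate the requested coefficients and confidence intervals.

        ``measures`` is ``"k"``, ``"alpha"`` or ``"both"``; ``ci`` is
        ``"asymptotic"`` (Fleiss' K only), ``"bootstrap"``, ``"both"`` or
        ``"none"``.  ``seed`` drives all resampling.
        """
        if measures not in _MEASURES:
            raise ValidationError(f"measures must be one of {sorted(_MEASURES)}")
        if ci not in _CI_CHOICES:
            raise ValidationError(f"ci must be one of {_CI_CHOICES}")
        wanted = _MEASURES[measures]
        if ci in ("asymptotic", "both") and "fleiss_k" not in wanted:
            raise ValidationError(
                "no asymptotic interval exists for Krippendorff's alpha "
                "(its distribution is unknown); use bootstrap"
            )
        if ci in ("asymptotic", "both"):
            warnings.warn(
                "the asymptotic interval for Fleiss' K is valid only for testing "
                "K = 0; off the null it is too narrow — prefer the bootstrap",
                UserWarning,
                stacklevel=2,
            )
        settings = CISettings(level=level, n_boot=n_boot, seed=seed)
        metric = metric_for(self.ratings.scale)

        estimates: dict[str, AgreementEstimate] = {}
        conf_ints: dict[tuple[str, str], ConfidenceInterval] = {}
        boot: dict[tuple[str, str], BootstrapDistribution] = {}
        se = None
        ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
        children = iter(ss.spawn(4))

        if "fleiss_k" in wanted:
            estimates["fleiss_k"] = fleiss_k_from_ratings(self.ratings)
            if ci in ("asymptotic", "both"):
                se = fleiss_k_se(count_matrix(self.ratings))
                conf_ints[("fleiss_k", "asymptotic")] = asymptotic_ci(
                    estimates["fleiss_k"].value, se, settings
                )
            if ci in ("bootstrap", "both"):
                s = CISettings(level=level, n_boot=n_boot, seed=next(children))
                dist, interval = subject_bootstrap(self.ratings, "fleiss_k", settings=s)
                boot[("fleiss_k", "subject_bootstrap")] = dist
                conf_ints[("fleiss_k", "subject_bootstrap")] = interval
        if "krippendorff_alpha" in wanted:
            estimates["krippendorff_alpha"] = alpha_from_ratings(self.ratings, metric)
            if ci in ("bootstrap", "both"):
                s = CISettings(level=level, n_boot=n_boot, seed=next(children))
                dist, interval = subject_bootstrap(
                    self.ratings, "krippendorff_alpha", metric, settings=s
                )
                boot[("krippendorff_alpha", "subject_bootstrap")] = dist
                conf_ints[("krippendorff_alpha", "subject_bootstrap")] = interval
            if include_coincidence_bootstrap:
                s = CISettings(level=level, n_boot=n_boot, seed=next(children))
                dist, interval = coincidence_bootstrap(self.ratings, metric, settings=s)
                boot[("krippendorff_alpha", "coincidence_bootstrap")] = dist
                conf_ints[("krippendorff_alpha", "coincidence_bootstrap")] = interval

        return AgreementResults(
            model=self,
            estimates=estimates,
            conf_ints=conf_ints,
            bootstrap_distributions=boot,
            fleiss_se=se,
            settings=settings,
        )


@dataclass
class AgreementResults:
    """Fitted agreement coefficients with uncertainty.

    Attributes
    ----------
    estimates
        Mapping ``measure -> AgreementEstimate``.
    conf_ints
        Mapping ``(measure, ci_method) -> ConfidenceInterval``.
    bootstrap_distributions
        Mapping ``(measure, ci_method) -> BootstrapDistribution``.
    """

    model: InterRaterReliability
    estimates: dict[str, AgreementEstimate]
    conf_ints: dict[tuple[str, str], ConfidenceInterval]
    bootstrap_distributions: dict[tuple[str, str], BootstrapDistribution]
    fleiss_se: float | None
    settings: CISettings
    _labels: dict = field(
        default_factory=lambda: {
            "fleiss_k": "Fleiss' K",
            "krippendorff_alpha": "Krippendorff's alpha",
        },
        repr=False,
    )

    @property
    def fleiss_k(self) -> float:
        return self.estimates["fleiss_k"].value

    @property
    def alpha(self) -> float:
        return self.estimates["krippendorff_alpha"].value

    def conf_int(self, measure: str, method: str | None = None) -> ConfidenceInterval:
        if method is None:
            for (m, meth), ci in self.conf_ints.items():
                if m == measure:
                    return ci
            raise KeyError(f"no confidence interval fitted for {measure!r}")
        return self.conf_ints[(measure, method)]

    def hypothesis_flags(self, measure: str, thresholds=(0.0, 0.6), method: str | None = None):
        """One-sided conclusions: is the CI's lower limit above each threshold?"""
        return hypothesis_flags(self.conf_int(measure, method), thresholds)

    def summary(self) -> str:
        """Human-readable summary table of estimates and intervals."""
        rt = self.model.ratings
        lines = [
            "Inter-rater reliability",
            "=" * 70,
            f"subjects: {rt.n_subjects}   raters: {rt.n_raters}   "
            f"categories: {rt.k} ({rt.scale})   missing cells: {rt.n_missing}",
            f"CI level: {self.settings.level:.0%}   bootstrap replicates: "
            f"{self.settings.n_boot}",
            "-" * 70,
            f"{'measure':<24}{'estimate':>10}  {'interval':<22}{'method':<20}",
        ]
        for measure, est in self.estimates.items():
            name = self._labels.get(measure, measure)
            flag = " (degenerate)" if est.degenerate_flag else ""
            printed = False
            for (m, meth), interval in self.conf_ints.items():
                if m != measure:
                    continue
                lines.append(
                    f"{name:<24}{est.value:>10.4f}  "
                    f"[{interval.lower: .4f}, {interval.upper: .4f}]  {meth:<20}"
                )
                printed = True
            if not printed:
                lines.append(f"{name:<24}{est.value:>10.4f}{flag}")
            if est.degenerate_flag and printed:
                lines.append(f"{'':<24}{'':>10}  single category used: value by convention")
            lines.append(
                f"{'':<24}subjects used: {est.n_subjects_used} / {rt.n_subjects}"
            )
        lines.append("=" * 70)
        return "\n".join(lines)

    def plot_bootstrap(self, measure: str = "krippendorff_alpha", ax=None):
        """Histogram of bootstrap replicates with the percentile CI marked."""
        import matplotlib.pyplot as plt

        key = next(
            (k for k in self.bootstrap_distributions if k[0] == measure), None
        )
        if key is None:
            raise KeyError(f"no bootstrap distribution fitted for {measure!r}")
        dist = self.bootstrap_distributions[key]
        interval = self.conf_ints[key]
        if ax is None:
            _, ax = plt.subplots()
        ax.hist(dist.estimates, bins=40, color="steelblue", alpha=0.8)
        ax.axvline(self.estimates[measure].value, color="black", label="estimate")
        ax.axvline(interval.lower, color="firebrick", ls="--", label="percentile CI")
        ax.axvline(interval.upper, color="firebrick", ls="--")
        ax.set_xlabel(self._labels.get(measure, measure))
        ax.set_ylabel("bootstrap replicates")
        ax.legend()
        return ax
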