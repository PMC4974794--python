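"""Monte-Carlo engine: bias and coverage of agreement coefficients.

The generator is a latent-class model with rater misclassification.  Each
subject carries a latent category ``T ~ Categorical(pi)``; each rater
independently reports ``T`` with fidelity probability ``gamma`` and otherwise
an independent draw from ``Categorical(pi)``.  Because the error draws come
from the same ``pi``, every rating is marginally ``Categorical(pi)`` —
i.i.d. multinomial margins — while ``gamma`` controls the within-subject
dependence and hence the true agreement.  A plain i.i.d. multinomial table
would pin the true coefficients at 0; the latent class is what moves them
into the studied 0.40-0.93 range.

Closed-form population values exist for this generator (``true_fleiss_k``,
``true_alpha``), so bias and empirical coverage can be measured exactly.
The factorial study grid crosses N in {50, 100, 200}, n in {3, 5, 10},
k in {2, 3, 5} and agreement strength low/moderate/high (81 scenarios);
three named N = 100 scenarios are additionally subjected to
missing-completely-at-random (MCAR) cell deletion at 10 / 25 / 50 %.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .estimators import alpha_from_ratings, count_matrix, fleiss_k, fleiss_k_se, metric_for
from .exceptions import DegenerateDataWarning, EstimationError, ValidationError
from .intervals import CISettings, asymptotic_ci, coincidence_bootstrap, subject_bootstrap
from .ratings import MISSING, RatingTable

#: Default category-probability vectors, honoring probabilities in [0.1, 0.5].
DEFAULT_PI = {
    2: (0.5, 0.5),
    3: (0.2, 0.3, 0.5),
    5: (0.1, 0.15, 0.2, 0.25, 0.3),
}

#: True Fleiss' K anchors for the three agreement strengths.
AGREEMENT_ANCHORS = {"low": 0.40, "moderate": 0.70, "high": 0.90}

#: Estimation methods the engine can evaluate per run.
METHODS = ("alpha_bootstrap", "k_bootstrap", "k_asymptotic", "alpha_coincidence")


@dataclass(frozen=True)
class Scenario:
    """One simulation condition: size, raters, categories and true agreement."""

    N: int
    n_raters: int
    k: int
    agreement: str            # "low" | "moderate" | "high"
    pi: tuple[float, ...]
    gamma: float
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.pi) != self.k:
            raise ValidationError("pi must have k entries")
        if abs(sum(self.pi) - 1.0) > 1e-9:
            raise ValidationError("pi must sum to 1")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValidationError("gamma must lie in [0, 1]")
        if not self.name:
            object.__setattr__(
                self, "name", f"N{self.N}_n{self.n_raters}_k{self.k}_{self.agreement}"
            )

    @property
    def true_values(self) -> "TrueValues":
        k_true = true_fleiss_k(self.pi, self.gamma)
        return TrueValues(
            k_true=k_true, alpha_true=true_alpha(self.pi, self.gamma, self.N, self.n_raters)
        )


@dataclass(frozen=True)
class TrueValues:
    k_true: float
    alpha_true: float


@dataclass(frozen=True)
class MissingDesign:
    """MCAR deletion of a fixed share of cells: exactly floor(p * N * n) cells."""

    proportion: float = 0.0
    mechanism: str = "MCAR"

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion < 1.0:
            raise ValidationError("missing proportion must lie in [0, 1)")
        if self.mechanism != "MCAR":
            raise ValidationError("only MCAR deletion is supported")


@dataclass(frozen=True)
class MethodSummary:
    """Aggregated performance of one estimator/CI combination in a scenario."""

    mean_estimate: float
    mean_bias_pct: float
    coverage_pct: float
    runs: int          # successful runs entering the aggregates
    failures: int
    mean_ci_width: float


@dataclass(frozen=True)
class ScenarioResult:
    scenario: Scenario
    missing: MissingDesign
    true_values: TrueValues
    methods: dict[str, MethodSummary]
    runs_requested: int


# ---------------------------------------------------------------------------
# Population values of the generator
# ---------------------------------------------------------------------------

def _check_pi(pi) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.ndim != 1 or len(pi) < 2:
        raise ValidationError("pi must be a probability vector over >= 2 categories")
    if (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-9:
        raise ValidationError("pi must be non-negative and sum to 1")
    if np.square(pi).sum() >= 1.0 - 1e-12:
        raise ValidationError("pi is degenerate (a single category has probability 1)")
    return pi


def true_fleiss_k(pi, gamma: float) -> float:
    """Population Fleiss' K of the latent-class generator.

    With ``q_j(t) = gamma * 1[j = t] + (1 - gamma) * pi_j`` (the rating
    distribution given latent class t), the probability that two raters
    agree is ``P_a = sum_t pi_t sum_j q_j(t)^2``; the chance term is
    ``P_e = sum_j pi_j^2`` (ratings are marginally Categorical(pi)), and
    ``K = (P_a - P_e) / (1 - P_e)``.
    """
    pi = _check_pi(pi)
    q = (1.0 - gamma) * pi[None, :] + gamma * np.eye(len(pi))
    p_a = float(pi @ np.square(q).sum(axis=1))
    p_e = float(np.square(pi).sum())
    return (p_a - p_e) / (1.0 - p_e)


def true_alpha(pi, gamma: float, N: int, n_raters: int) -> float:
    """Population Krippendorff's alpha at the scenario's pairable total n.. = N * n.

    Exact finite-sample correction for complete nominal data:
    ``alpha = 1 - (1 - K) * (n.. - 1) / n..``.
    """
    n_tot = N * n_raters
    return 1.0 - (1.0 - true_fleiss_k(pi, gamma)) * (n_tot - 1.0) / n_tot


def calibrate_gamma(pi, target_k: float) -> float:
    """Fidelity gamma such that ``true_fleiss_k(pi, gamma) == target_k`` (to 1e-9).

    ``true_fleiss_k`` is strictly increasing in gamma with K(0) = 0 and
    K(1) = 1, so the root is unique.
    """
    _check_pi(pi)
    if not 0.0 <= target_k < 1.0:
        raise ValidationError("target Fleiss' K must lie in [0, 1)")
    if target_k == 0.0:
        return 0.0
    gamma = float(
        optimize.brentq(lambda g: true_fleiss_k(pi, g) - target_k, 0.0, 1.0, xtol=1e-13)
    )
    return gamma


def make_scenario(N: int, n_raters: int, k: int, agreement: str, pi=None, name: str = "") -> Scenario:
    """Build a scenario with default category probabilities and calibrated gamma."""
    if agreement not in AGREEMENT_ANCHORS:
        raise ValidationError(f"agreement must be one of {sorted(AGREEMENT_ANCHORS)}")
    if pi is None:
        try:
            pi = DEFAULT_PI[k]
        except KeyError:
            raise ValidationError(f"no default pi for k={k}; pass pi explicitly") from None
    gamma = calibrate_gamma(pi, AGREEMENT_ANCHORS[agreement])
    return Scenario(N=N, n_raters=n_raters, k=k, agreement=agreement,
                    pi=tuple(pi), gamma=gamma, name=name)


# ---------------------------------------------------------------------------
# Data generation
# ---------------------------------------------------------------------------

def latent_class_sample(scenario: Scenario, seed) -> RatingTable:
    """Draw one complete N x n rating table from the latent-class generator."""
    rng = np.random.default_rng(seed)
    N, n, k = scenario.N, scenario.n_raters, scenario.k
    pi = np.asarray(scenario.pi)
    latent = rng.choice(k, size=N, p=pi)
    noise = rng.choice(k, size=(N, n), p=pi)
    faithful = rng.random((N, n)) < scenario.gamma
    values = np.where(faithful, latent[:, None], noise) + 1
    return RatingTable(values=values.astype(np.int64), k=k)


def apply_mcar(ratings: RatingTable, design: MissingDesign, seed) -> RatingTable:
    """Delete exactly floor(p * N * n) cells, uniformly without replacement."""
    if ratings.n_missing:
        raise ValidationError("MCAR deletion expects a complete rating table")
    if design.proportion == 0.0:
        return ratings
    rng = np.random.default_rng(seed)
    n_cells = ratings.n_subjects * ratings.n_raters
    n_delete = int(np.floor(design.proportion * n_cells))
    flat = ratings.values.copy().ravel()
    flat[rng.choice(n_cells, size=n_delete, replace=False)] = MISSING
    return RatingTable(
        values=flat.reshape(ratings.values.shape),
        k=ratings.k,
        scale=ratings.scale,
        categories=ratings.categories,
    )


# ---------------------------------------------------------------------------
# Scenario execution
# ---------------------------------------------------------------------------

def _scenario_entropy(scenario: Scenario, missing: MissingDesign) -> int:
    key = (
        f"{scenario.N}|{scenario.n_raters}|{scenario.k}|{scenario.agreement}|"
        f"{scenario.pi}|{missing.proportion}"
    )
    return zlib.crc32(key.encode())


def run_scenario(
    scenario: Scenario,
    missing: MissingDesign = MissingDesign(0.0),
    runs: int = 1000,
    ci_settings: CISettings | None = None,
    master_seed: int = 0,
    methods: tuple[str, ...] = ("alpha_bootstrap", "k_bootstrap", "k_asymptotic"),
) -> ScenarioResult:
    """Simulate, delete, estimate and aggregate bias / coverage per method.

    Per run: draw a table, apply MCAR deletion, estimate alpha (all subjects
    with >= 2 ratings) and complete-case Fleiss' K, and build the requested
    95 % CIs.  Bias is reported as a percentage of the matching true value
    (``alpha_true`` for alpha, ``k_true`` for K); coverage is the share of
    runs whose CI contains it.  Child seeds derive deterministically from
    ``master_seed`` and the scenario identity.
    """
    if runs < 1:
        raise ValidationError("at least one simulation run is required")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValidationError(f"unknown methods: {sorted(unknown)}")
    ci_settings = ci_settings or CISettings()
    tv = scenario.true_values
    metric = metric_for("nominal")

    need_alpha_boot = "alpha_bootstrap" in methods
    need_k = "k_bootstrap" in methods or "k_asymptotic" in methods
    need_coinc = "alpha_coincidence" in methods

    est: dict[str, list[float]] = {m: [] for m in methods}
    cover: dict[str, list[bool]] = {m: [] for m in methods}
    width: dict[str, list[float]] = {m: [] for m in methods}
    failures: dict[str, int] = {m: 0 for m in methods}

    root = np.random.SeedSequence([master_seed, _scenario_entropy(scenario, missing)])
    children = root.spawn(runs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateDataWarning)
        for child in children:
            data_ss, a_ss, k_ss, c_ss = child.spawn(4)
            table = latent_class_sample(scenario, data_ss)
            if missing.proportion > 0.0:
                table = apply_mcar(table, missing, data_ss.spawn(1)[0])

            if need_alpha_boot or need_coinc:
                try:
                    a_hat = alpha_from_ratings(table, metric).value
                except EstimationError:
                    a_hat = None
                if need_alpha_boot:
                    _record_alpha_boot(
                        table, metric, ci_settings, a_ss, a_hat, tv.alpha_true,
                        est, cover, width, failures,
                    )
                if need_coinc:
                    _record_coinc_boot(
                        table, metric, ci_settings, c_ss, a_hat, tv.alpha_true,
                        est, cover, width, failures,
                    )
            if need_k:
                _record_k(
                    table, ci_settings, k_ss, tv.k_true, methods,
                    est, cover, width, failures,
                )

    summaries: dict[str, MethodSummary] = {}
    for m in methods:
        ok = len(est[m])
        if failures[m] > 0.01 * runs:
            warnings.warn(
                f"{failures[m]} of {runs} runs failed for method {m} in "
                f"scenario {scenario.name} ({missing.proportion:.0%} missing)",
                UserWarning,
                stacklevel=2,
            )
        truth = tv.k_true if m.startswith("k_") else tv.alpha_true
        mean_est = float(np.mean(est[m])) if ok else float("nan")
        summaries[m] = MethodSummary(
            mean_estimate=mean_est,
            mean_bias_pct=100.0 * (mean_est - truth) / truth if ok else float("nan"),
            coverage_pct=100.0 * float(np.mean(cover[m])) if ok else float("nan"),
            runs=ok,
            failures=failures[m],
            mean_ci_width=float(np.mean(width[m])) if ok else float("nan"),
        )
    return ScenarioResult(
        scenario=scenario, missing=missing, true_values=tv,
        methods=summaries, runs_requested=runs,
    )


def _record_alpha_boot(table, metric, ci_settings, ss, a_hat, truth,
                       est, cover, width, failures) -> None:
    if a_hat is None:
        failures["alpha_bootstrap"] += 1
        return
    try:
        s = CISettings(level=ci_settings.level, n_boot=ci_settings.n_boot, seed=ss)
        _, ci = subject_bootstrap(table, "krippendorff_alpha", metric, settings=s)
    except EstimationError:
        failures["alpha_bootstrap"] += 1
        return
    est["alpha_bootstrap"].append(a_hat)
    cover["alpha_bootstrap"].append(ci.contains(truth))
    width["alpha_bootstrap"].append(ci.upper - ci.lower)


def _record_coinc_boot(table, metric, ci_settings, ss, a_hat, truth,
                       est, cover, width, failures) -> None:
    if a_hat is None:
        failures["alpha_coincidence"] += 1
        return
    try:
        s = CISettings(level=ci_settings.level, n_boot=ci_settings.n_boot, seed=ss)
        _, ci = coincidence_bootstrap(table, metric, settings=s)
    except EstimationError:
        failures["alpha_coincidence"] += 1
        return
    est["alpha_coincidence"].append(a_hat)
    cover["alpha_coincidence"].append(ci.contains(truth))
    width["alpha_coincidence"].append(ci.upper - ci.lower)


def _record_k(table, ci_settings, ss, truth, methods,
              est, cover, width, failures) -> None:
    counts = count_matrix(table)
    try:
        k_hat = fleiss_k(counts).value
    except EstimationError:
        for m in ("k_bootstrap", "k_asymptotic"):
            if m in methods:
                failures[m] += 1
        return
    if "k_bootstrap" in methods:
        try:
            s = CISettings(level=ci_settings.level, n_boot=ci_settings.n_boot, seed=ss)
            _, ci = subject_bootstrap(table, "fleiss_k", settings=s)
            est["k_bootstrap"].append(k_hat)
            cover["k_bootstrap"].append(ci.contains(truth))
            width["k_bootstrap"].append(ci.upper - ci.lower)
        except EstimationError:
            failures["k_bootstrap"] += 1
    if "k_asymptotic" in methods:
        try:
            se = fleiss_k_se(counts)
            ci = asymptotic_ci(k_hat, se, ci_settings)
            est["k_asymptotic"].append(k_hat)
            cover["k_asymptotic"].append(ci.contains(truth))
            width["k_asymptotic"].append(ci.upper - ci.lower)
        except EstimationError:
            failures["k_asymptotic"] += 1


# ---------------------------------------------------------------------------
# Scenario grids
# ---------------------------------------------------------------------------

#: The three named MCAR scenarios (all with N = 100).
MISSING_SCENARIOS = {
    "I": dict(N=100, n_raters=5, k=2, agreement="low"),
    "II": dict(N=100, n_raters=5, k=5, agreement="high"),
    "III": dict(N=100, n_raters=10, k=3, agreement="moderate"),
}

MISSING_PROPORTIONS = (0.10, 0.25, 0.50)


def scenario_grid(kind: str = "full") -> list[tuple[Scenario, MissingDesign]]:
    """Enumerate the study conditions.

    ``"full"`` — the 3 x 3 x 3 x 3 factorial grid (81 complete-data
    scenarios).  ``"missing"`` — the three named N = 100 scenarios crossed
    with MCAR proportions 10 / 25 / 50 % (9 entries).
    """
    if kind == "full":
        grid = []
        for N in (50, 100, 200):
            for n in (3, 5, 10):
                for k in (2, 3, 5):
                    for agreement in ("low", "moderate", "high"):
                        grid.append((make_scenario(N, n, k, agreement), MissingDesign(0.0)))
        return grid
    if kind == "missing":
        return [
            (make_scenario(name=name, **spec), MissingDesign(prop))
            for name, spec in MISSING_SCENARIOS.items()
            for prop in MISSING_PROPORTIONS
        ]
    raise ValidationError(f"unknown grid kind {kind!r}; use 'full' or 'missing'")


def results_to_records(results) -> list[dict]:
    """Flatten ScenarioResults to one record per scenario x missing level x method."""
    records = []
    for res in results:
        for method, summ in res.methods.items():
            records.append(
                {
                    "scenario": res.scenario.name,
                    "N": res.scenario.N,
                    "n_raters": res.scenario.n_raters,
                    "k": res.scenario.k,
                    "agreement": res.scenario.agreement,
                    "missing_pct": 100.0 * res.missing.proportion,
                    "method": method,
                    "true_k": res.true_values.k_true,
                    "true_alpha": res.true_values.alpha_true,
                    "mean_estimate": summ.mean_estimate,
                    "mean_bias_pct": summ.mean_bias_pct,
                    "coverage_pct": summ.coverage_pct,
                    "mean_ci_width": summ.mean_ci_width,
                    "runs": summ.runs,
                    "failures": summ.failures,
                }
            )
    return records
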