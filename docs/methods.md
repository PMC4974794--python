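# Methods

## Coefficients

Both coefficients compare the agreement observed among raters with the
agreement a guessing process with the same category marginals would produce.

**Fleiss' K** operates on the per-subject tallies n_ij (raters assigning
subject i to category j). Mean within-subject pair agreement
P̄ = mean_i (Σ_j n_ij² − n)/(n(n−1)) is corrected by the chance term
P_e = Σ_j p_j², where p_j are the pooled marginal proportions, giving
K = (P̄ − P_e)/(1 − P_e). The chance term treats the marginals as known
(infinite-sample), and the statistic is defined only on subjects rated by
all n raters: estimation silently performs complete-case deletion and
reports how many subjects survived. The Fleiss–Nee–Landis standard error

    se(K̂) = sqrt(2/(N n(n−1))) · sqrt((Σ_j q_j)² − Σ_j q_j(1−2p_j)) / Σ_j q_j,
    q_j = p_j(1 − p_j)

is a null-hypothesis (K = 0) quantity. The asymptotic interval
K̂ ± z_{1−α/2} se(K̂) is therefore reported with a warning and is not
truncated to [−1, 1]; away from the null its width is unrelated to the
estimator's true sampling spread (it can be both too narrow and too wide —
see "Limitations").

**Krippendorff's alpha** operates on the coincidence matrix: each subject
with m_u ≥ 2 ratings contributes o_cc' += n_uc n_uc' /(m_u − 1) for c ≠ c'
and o_cc += n_uc(n_uc − 1)/(m_u − 1), so each of its m_u pairable values is
counted exactly once in n.. = Σ_u m_u. Observed disagreement
D_o = Σ o_cc' δ(c,c')/n.. is corrected by the finite-sample chance term
D_e = Σ n_c n_c' δ(c,c')/(n..(n.. − 1)); α = 1 − D_o/D_e. Subjects with
fewer than two ratings are excluded (and counted). Distance metrics:
nominal δ = 1[c ≠ c']; ordinal δ(c,c') = (Σ_{g=c}^{c'} n_g − (n_c+n_c')/2)²,
computed from the retained-data marginals (Krippendorff's convention), not
from user weights. Category ranks are the positions in the user-supplied
category order; codes are 1-based internally.

On complete nominal data the two estimators satisfy the exact identity
1 − α̂ = (1 − K̂)(n.. − 1)/n.. with n.. = N·n; the test suite asserts it to
1e-10 on random tables, and it propagates to the population values of the
simulation generator.

**Degenerate data.** When every retained rating falls in a single category
both coefficients are 0/0. The package returns 1.0 with a `degenerate_flag`
and a `DegenerateDataWarning`: agreement is trivially perfect, and the
convention keeps bootstrap replicates well-defined instead of forcing
replicate-level failures. Degenerate replicates are counted and reported
(`BootstrapDistribution.n_degenerate`).

## Confidence intervals

* **Subject bootstrap** (both coefficients): B replicates, each drawing
  subjects with replacement while keeping every rater's value inside a drawn
  subject, preserving the rater dependence. The interval is read from
  1-based order statistics at ceil(B·α/2) and ceil(B(1−α/2)) — for B = 1000
  and α = 0.05, replicates 25 and 975. The ceiling convention matters only
  when B·α/2 is non-integral; a small numeric guard keeps exact-integer
  cases on the intended order statistic. For Fleiss' K the complete-case
  deletion happens **before** resampling: the bootstrap resamples the
  N_retained complete observations, i.e. the dataset K actually sees. (The
  alternative — resampling all N rows and re-deleting per replicate — was
  considered and rejected: K's procedure is defined on the complete-case
  dataset, and deletion-first matches how the estimator is used in
  practice.) Inestimable replicates are redrawn, up to 100 passes, then the
  run aborts with a diagnostic.
* **Coincidence bootstrap** (alpha only, for comparison): the expected
  disagreement D_e — and, for the ordinal metric, the distance matrix — is
  frozen at its full-data value; each replicate draws
  M = Σ_u m_u(m_u−1)/2 coincidences (one per distinct within-subject
  comparison, so subjects with more ratings weigh proportionally more) from
  the cell distribution o_cc'/n.. and recomputes only D_o. Resampling pairs
  independently discards the within-subject dependence, which is precisely
  why this construction under-covers; the simulation engine measures the
  shortfall. The published description of the original algorithm fixes only
  its three deviations from the standard bootstrap (rating-count weighting,
  resampling from the coincidence matrix, fixed D_e); the per-replicate draw
  count is this package's choice, so the measured coverage characterizes
  this variant, not any particular macro implementation bit-for-bit.
* **No BCa/studentized intervals** — plain percentile only, matching the
  procedure under study.

All resampling is driven by `numpy.random.Generator`; a seed fully
determines every interval.

## Simulation engine

**Generator.** Plain i.i.d. multinomial ratings have true agreement 0, so
controllable agreement is induced by a latent class: subject i carries
T_i ~ Categorical(π); each rater reports T_i with fidelity probability γ and
otherwise an independent draw from Categorical(π). Error draws reuse π, so
every rating is marginally Categorical(π) and the marginal distribution
stays multinomial. Closed forms follow: with q_j(t) = γ·1[j=t] + (1−γ)π_j,

    P_a = Σ_t π_t Σ_j q_j(t)²,  P_e = Σ_j π_j²,  K_true = (P_a − P_e)/(1 − P_e),
    α_true = 1 − (1 − K_true)(n.. − 1)/n..,  n.. = N·n.

K_true is strictly increasing in γ (K(0)=0, K(1)=1), so `calibrate_gamma`
root-finds γ for a target coefficient to 1e-9 (Brent's method).

**Defaults.** Category probabilities honour the 0.1–0.5 range:
k=2 → (0.5, 0.5) (forced: two probabilities in [0.1, 0.5] must be equal),
k=3 → (0.2, 0.3, 0.5), k=5 → (0.1, 0.15, 0.2, 0.25, 0.3). Agreement anchors
on the K scale: low 0.40, moderate 0.70, high 0.90 — inside the studied
0.40–0.93 range; the exact per-scenario values of the original study are
unpublished. The factorial grid crosses N ∈ {50, 100, 200}, n ∈ {3, 5, 10},
k ∈ {2, 3, 5} and the three agreement levels (81 scenarios). The
missing-data grid uses the three named N = 100 scenarios (I: n=5, k=2, low;
II: n=5, k=5, high; III: n=10, k=3, moderate) at 10/25/50 % deletion.

**MCAR deletion** removes exactly floor(p·N·n) cells, uniformly without
replacement — missingness independent of everything, the cleanest MCAR
mechanism. MAR/MNAR are out of scope.

**Evaluation.** Per run the engine simulates, deletes, estimates alpha (all
subjects with ≥ 2 ratings) and complete-case K, and builds the requested
95 % intervals (defaults: 1,000 runs × 1,000 bootstrap replicates, two-sided
α = 0.05). Percentage bias is 100·(mean estimate − true)/true against
α_true for alpha and K_true for K (under MCAR the complete cases are a
random subsample, so the complete-case estimand equals K_true). Coverage is
the share of runs whose interval contains the true value. Runs where an
estimator is inestimable (e.g. fewer than two complete cases) count as
failures, are excluded from that method's aggregates, and trigger a warning
above 1 %. Seeds: a `SeedSequence` keyed on (master seed, scenario identity)
spawns one child per run; each run spawns separate streams for data
generation, MCAR deletion and each bootstrap, so any subset of methods is
reproducible independently of the others.

**Problem sizes used by the shipped checks.** The test suite runs its
Monte-Carlo checks at 1,000 runs × 500 replicates (400 × 400 for the
direction-only comparisons); `scripts/acceptance.py` uses the full
1,000 × 1,000, with 5,000 runs for the scenario-III Fleiss-K cell at 50 %
missingness — there a subject survives complete-case deletion with
probability 0.5¹⁰ ≈ 0.001, so with 1,000 runs that cell would rest on a
handful of estimable runs; extra runs reduce the Monte-Carlo noise of an
unchanged estimand.

## What the generator does and does not emulate

It reproduces the structural features the coefficients respond to:
exchangeable raters, within-subject dependence with tunable strength,
multinomial marginals, and MCAR missingness. It does not emulate rater
heterogeneity (systematically lenient/strict raters), prevalence "paradox"
configurations with rare categories, ordinal measurement error (the
simulation study is nominal; ordinal metrics are exercised on fixtures),
or informative missingness. Passing simulation checks therefore support the
estimators' behaviour under exchangeable-rater MCAR conditions, not under
rater bias or MAR/MNAR dropout.

Two consequences are worth flagging for anyone comparing against published
missing-data tables. First, at heavy missingness the complete-case K
summaries are conditional on the rare event "≥ 2 complete cases"; with 2–6
surviving subjects the small-sample distribution of K̂ (and hence bias and
coverage in those cells) depends strongly on fine generator details —
e.g. the chance that the few survivors share a latent class, and the
degenerate → 1.0 convention. Different generators that match all the
published study parameters can legitimately disagree by tens of points in
those cells, while the alpha cells (which use all subjects with ≥ 2
ratings) are stable and reproduce closely. Second, the package's true
values use the exact finite-sample relation between the two coefficients,
under which |K_true − α_true| = (1 − K_true)/(N·n); for the smallest grid
scenarios this gap reaches 4e-3 — a real property of alpha's finite-sample
chance term, not an implementation artefact.

## Numerical choices

* Invariant/degeneracy tolerance: 1e-10 relative (`estimators.TOL`);
  degeneracy of D_e is scale-aware for the ordinal metric.
* Percentile order statistics: ceiling convention with a 1e-9 guard (above).
* Bootstrap replicate redraw cap: 100 passes per batch of invalid replicates.
* `calibrate_gamma`: Brent root-finding on [0, 1], xtol 1e-13.
* Bootstrap internals represent a resample by its multiplicity vector
  (multinomial weights), so every replicate statistic is a single matrix
  product; a per-replicate expansion oracle in the tests verifies exact
  agreement with the literal "resample rows and re-estimate" definition.

## Known limitations

* Complete-data K̂ carries the usual O(1/N) negative bias (the plug-in
  chance term is estimated); at N = 50 it is of order 0.5 % of the
  coefficient — visible against tight Monte-Carlo tolerances even though it
  is immaterial in practice.
* The asymptotic interval's coverage depends on where the truth lies: its
  null-based width under-covers at low/moderate agreement and can
  over-cover at high agreement with few categories. The package keeps it
  for comparability and warns on use; the bootstrap interval is the
  recommended default.
* The coincidence bootstrap is a faithful-variant reconstruction (see
  above), implemented to quantify its structural undercoverage, not to
  reproduce any specific legacy macro numerically.
* Ordinal alpha uses Krippendorff's marginal-based metric only; interval,
  ratio and circular metrics, weighted Cohen-type kappas, and
  model-based alternatives (latent-class, quasi-symmetry, mixture models)
  are out of scope.
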