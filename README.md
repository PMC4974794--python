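# kalpha

Chance-corrected inter-rater agreement for categorical data, with honest
uncertainty.

When several raters independently assign the same subjects to categories —
pathologists re-reading biopsies, epidemiologists coding exposure status,
annotators labelling records — raw percent agreement overstates reliability,
because some agreement happens by guessing alone. `kalpha` implements the two
most flexible chance-corrected coefficients for this setting, both defined
for any number of raters (n ≥ 2) and categories (k ≥ 2):

* **Fleiss' K** (the multi-rater generalization of Scott's π). With
  per-subject category tallies *n<sub>ij</sub>*,

      P_i = (Σ_j n_ij² − n) / (n(n−1)),   P̄ = mean_i P_i,
      p_j = Σ_i n_ij / (N·n),             P_e = Σ_j p_j²,
      K   = (P̄ − P_e) / (1 − P_e).

  K requires complete data: subjects with fewer than *n* ratings are dropped
  (complete-case analysis). The Fleiss–Nee–Landis standard error and the
  asymptotic interval K̂ ± z<sub>1−α/2</sub>·se(K̂) are provided, with a
  warning: that standard error is valid only for testing K = 0.

* **Krippendorff's alpha**, built from the coincidence matrix of pairable
  values *o<sub>cc'</sub>* (each subject with m<sub>u</sub> ≥ 2 ratings
  contributes its within-subject value pairs, weighted by 1/(m<sub>u</sub>−1)):

      D_o = Σ_{c,c'} o_cc'·δ(c,c') / n..,
      D_e = Σ_{c,c'} n_c·n_c'·δ(c,c') / (n..(n..−1)),
      α   = 1 − D_o / D_e.

  Alpha tolerates missing ratings (any subject with at least two ratings
  contributes), uses the actual sample size in its chance term, and supports
  nominal and ordinal distance metrics δ.

Both coefficients live on [−1, 1]: 1 = perfect agreement, 0 = chance level,
negative = systematic disagreement.

Confidence intervals come from the **subject-resampling percentile
bootstrap** (subjects are redrawn with replacement, keeping each subject's
full rating vector, and the α/2 and 1−α/2 percentiles of the re-estimates
are reported). For comparison, Krippendorff's original
**coincidence-matrix bootstrap** is also implemented; because it resamples
individual value pairs and ignores the within-subject dependence between
raters, its intervals are systematically too narrow — the package's
simulation engine quantifies exactly how far its coverage falls below the
nominal level.

A **Monte-Carlo engine** generates rating tables with known true agreement
(a latent-class generator with calibrated rater fidelity), deletes cells
completely at random (MCAR), and measures percentage bias and empirical
coverage of every coefficient/interval combination over a 81-scenario
factorial grid (N ∈ {50, 100, 200}, n ∈ {3, 5, 10}, k ∈ {2, 3, 5},
agreement low/moderate/high) plus three missing-data scenarios at 10/25/50 %
deletion.

## Worked example

Four subjects, two raters, ratings (1,1), (1,1), (2,2), (1,2):

```python
import pandas as pd
from kalpha import InterRaterReliability

df = pd.DataFrame([[1, 1], [1, 1], [2, 2], [1, 2]])
res = InterRaterReliability.from_dataframe(df).fit(n_boot=1000, seed=42)
print(res.summary())
```

```
Inter-rater reliability
======================================================================
subjects: 4   raters: 2   categories: 2 (nominal)   missing cells: 0
CI level: 95%   bootstrap replicates: 1000
----------------------------------------------------------------------
measure                   estimate  interval              method
Fleiss' K                   0.4667  [-0.6000,  1.0000]  subject_bootstrap
                        subjects used: 4 / 4
Krippendorff's alpha        0.5333  [-0.4000,  1.0000]  subject_bootstrap
                        subjects used: 4 / 4
======================================================================
```

Mean observed agreement is P̄ = 0.75; chance agreement from the marginals
p = (0.625, 0.375) is P_e = 0.53125, so K̂ = (0.75 − 0.53125)/(1 − 0.53125)
= 0.4667. Alpha weighs the same information as disagreement with the
actual sample size n.. = 8, giving Â = 1 − 0.25/0.5357 = 0.5333; on complete
nominal data the two are linked exactly by 1 − Â = (1 − K̂)(n.. − 1)/n...
With only four subjects the bootstrap intervals are (correctly) very wide:

```python
res.hypothesis_flags("krippendorff_alpha", thresholds=(0.0, 0.6))
# {'above_0': False, 'above_0.6': False}
```

— the data cannot demonstrate better-than-chance reliability, let alone the
conventional "substantial" 0.6 threshold.

The same analysis from the shell, for a wide CSV (rows = subjects,
columns = raters; `""`, `NA` and `.` are missing by default):

```bash
kalpha estimate --input ratings.csv --measures both --ci bootstrap \
       --B 1000 --seed 42 --json-out report.json
kalpha fixtures --out fixtures/          # small reference tables + expected values
kalpha simulate --grid missing --runs 1000 --B 1000 --seed 1 --out results/missing
```

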