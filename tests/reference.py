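"""Independent brute-force reference implementations used only as test oracles.

Everything here works by explicit enumeration over subjects, raters and
category pairs — deliberately slow and structurally unrelated to the
vectorized implementation under test.
"""

from __future__ import annotations

import numpy as np


def pairwise_mean_agreement(values: np.ndarray) -> float:
    """Mean fraction of agreeing ordered rater pairs over complete-case subjects."""
    n = values.shape[1]
    per_subject = []
    for row in values:
        if (row == 0).any():
            continue
        agree = 0
        for a in range(n):
            for b in range(n):
                if a != b and row[a] == row[b]:
                    agree += 1
        per_subject.append(agree / (n * (n - 1)))
    return float(np.mean(per_subject))


def fleiss_k_bruteforce(values: np.ndarray, k: int) -> float:
    """Fleiss' K via explicit pair counting and complete-case marginals."""
    n = values.shape[1]
    complete = values[~(values == 0).any(axis=1)]
    p_bar = pairwise_mean_agreement(complete)
    marg = np.zeros(k)
    for row in complete:
        for v in row:
            marg[v - 1] += 1
    p = marg / marg.sum()
    p_e = float((p**2).sum())
    return (p_bar - p_e) / (1.0 - p_e)


def coincidence_bruteforce(values: np.ndarray, k: int) -> np.ndarray:
    """Coincidence matrix via enumeration of ordered within-subject pairs."""
    o = np.zeros((k, k))
    for row in values:
        obs = [v for v in row if v != 0]
        m = len(obs)
        if m < 2:
            continue
        for a in range(m):
            for b in range(m):
                if a != b:
                    o[obs[a] - 1, obs[b] - 1] += 1.0 / (m - 1)
    return o


def alpha_bruteforce(values: np.ndarray, k: int, kind: str = "nominal") -> float:
    """Krippendorff's alpha from the brute-force coincidence matrix."""
    o = coincidence_bruteforce(values, k)
    marg = o.sum(axis=1)
    n_tot = o.sum()
    if kind == "nominal":
        delta = 1.0 - np.eye(k)
    else:
        delta = np.zeros((k, k))
        for c in range(1, k + 1):
            for cp in range(1, k + 1):
                lo, hi = sorted((c, cp))
                delta[c - 1, cp - 1] = (
                    marg[lo - 1 : hi].sum() - (marg[lo - 1] + marg[hi - 1]) / 2.0
                ) ** 2
    d_o = sum(
        o[c, cp] * delta[c, cp] for c in range(k) for cp in range(k)
    ) / n_tot
    d_e = sum(
        marg[c] * marg[cp] * delta[c, cp] for c in range(k) for cp in range(k)
    ) / (n_tot * (n_tot - 1.0))
    return 1.0 - d_o / d_e


def fleiss_se_transcription(counts: np.ndarray, n: int) -> float:
    """Separate, literal transcription of the Fleiss-Nee-Landis variance formula."""
    counts = counts[counts.sum(axis=1) == n]
    big_n = counts.shape[0]
    p = counts.sum(axis=0) / (big_n * n)
    q = [pj * (1 - pj) for pj in p]
    s = sum(q)
    inner = s**2 - sum(qj * (1 - 2 * pj) for qj, pj in zip(q, p))
    return float(np.sqrt(2.0 / (big_n * n * (n - 1))) * np.sqrt(inner) / s)


def random_table(rng: np.random.Generator, n_subjects, n_raters, k, missing_frac=0.0,
                 agreement=0.5):
    """A random rating table (integer codes, 0 = missing) with tunable clustering."""
    latent = rng.integers(1, k + 1, size=n_subjects)
    noise = rng.integers(1, k + 1, size=(n_subjects, n_raters))
    faithful = rng.random((n_subjects, n_raters)) < agreement
    values = np.where(faithful, latent[:, None], noise)
    if missing_frac > 0:
        mask = rng.random((n_subjects, n_raters)) < missing_frac
        values = np.where(mask, 0, values)
    return values.astype(np.int64)
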