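"""Independent brute-force oracles for the agreement statistics.

Everything here is written from the defining formulas with explicit loops,
deliberately sharing no code with the package implementation.
"""

import itertools

import numpy as np


def icc2_single_oracle(m: np.ndarray) -> float:
    """ICC(2,1) from two-way ANOVA mean squares, computed longhand."""
    m = np.asarray(m, float)
    n, k = m.shape
    grand = m.sum() / (n * k)
    row = [m[i].sum() / k for i in range(n)]
    col = [m[:, j].sum() / n for j in range(k)]
    ms_rows = k * sum((r - grand) ** 2 for r in row) / (n - 1)
    ms_cols = n * sum((c - grand) ** 2 for c in col) / (k - 1)
    ss_resid = 0.0
    for i in range(n):
        for j in range(k):
            ss_resid += (m[i, j] - row[i] - col[j] + grand) ** 2
    ms_resid = ss_resid / ((n - 1) * (k - 1))
    return (ms_rows - ms_resid) / (
        ms_rows + (k - 1) * ms_resid + k * (ms_cols - ms_resid) / n
    )


def fleiss_kappa_oracle(labels: np.ndarray) -> float:
    """Fleiss' kappa from observed vs chance agreement, computed longhand."""
    labels = np.asarray(labels, dtype=object)
    n_sub, n_rat = labels.shape
    cats = sorted({x for row in labels for x in row}, key=str)
    counts = [[sum(1 for x in row if x == c) for c in cats] for row in labels]
    p_j = [sum(counts[i][j] for i in range(n_sub)) / (n_sub * n_rat)
           for j in range(len(cats))]
    p_i = [
        (sum(c * c for c in counts[i]) - n_rat) / (n_rat * (n_rat - 1))
        for i in range(n_sub)
    ]
    p_bar = sum(p_i) / n_sub
    p_e = sum(p * p for p in p_j)
    return (p_bar - p_e) / (1 - p_e)


def cohen_kappa_oracle(r1, r2) -> float:
    """Cohen's kappa from the agreement table, computed longhand."""
    cats = sorted(set(r1) | set(r2), key=str)
    n = len(r1)
    p_o = sum(1 for a, b in zip(r1, r2) if a == b) / n
    p_e = sum(
        (sum(1 for a in r1 if a == c) / n) * (sum(1 for b in r2 if b == c) / n)
        for c in cats
    )
    return (p_o - p_e) / (1 - p_e)


def mean_pairwise_cohen_oracle(labels: np.ndarray) -> float:
    labels = np.asarray(labels, dtype=object)
    ks = [cohen_kappa_oracle(labels[:, i], labels[:, j])
          for i, j in itertools.combinations(range(labels.shape[1]), 2)]
    return float(np.mean(ks))
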