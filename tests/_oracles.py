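"""Independent brute-force oracles used to validate the package estimators.

These deliberately re-derive each quantity from first principles by a
different route than the library (literal ANOVA sums of squares, explicit
per-site loops), so agreement is informative.
"""

from __future__ import annotations

import numpy as np


def wc_fst_anova(dosage: np.ndarray, groups: np.ndarray) -> float:
    """Weir-Cockerham multi-site F_ST via literal ANOVA mean squares.

    Each allele copy is an observation x in {0, 1}; per site the among-
    population (a), among-individual (b), and within-individual (c)
    variance components come from the mean squares MSP, MSI, MSG, and the
    multi-site estimate is sum(a) / sum(a+b+c). ``dosage`` is samples x
    sites with -1 for missing; ``groups`` holds 0/1 labels.
    """
    num = 0.0
    den = 0.0
    for s in range(dosage.shape[1]):
        comp = _site_components(dosage[:, s], groups)
        if comp is None:
            continue
        a, b, c = comp
        num += a
        den += a + b + c
    return num / den if den != 0 else float("nan")


def _site_components(dos: np.ndarray, groups: np.ndarray):
    r = 2
    per_pop = []
    for g in (0, 1):
        d = dos[(groups == g) & (dos >= 0)]
        if len(d) < 2:
            return None
        per_pop.append(d.astype(float))
    n_i = np.array([len(d) for d in per_pop], dtype=float)
    n_tot = n_i.sum()
    # allele-level observations: individual j in pop i has copies summing
    # to dosage; represent as (x1, x2) with x1 + x2 = dosage, het = (0, 1)
    xbar_i = np.array([d.mean() / 2.0 for d in per_pop])
    xbar = float(sum(d.sum() / 2.0 for d in per_pop) / n_tot)
    # within-individual sum of squares: for dosage 1 the two copies are 0,1
    # (deviation 0.5 each); for dosage 0 or 2 both copies equal their mean
    ssg = sum(float(np.sum(d == 1)) * 0.5 for d in per_pop)
    msg = ssg / n_tot
    ssi = 0.0
    for d, xb in zip(per_pop, xbar_i):
        ssi += float(np.sum(2.0 * (d / 2.0 - xb) ** 2))
    msi = ssi / (n_tot - r)
    ssp = float(np.sum(2.0 * n_i * (xbar_i - xbar) ** 2))
    msp = ssp / (r - 1)
    n_c = (n_tot - np.sum(n_i**2) / n_tot) / (r - 1)
    a = (msp - msi) / (2.0 * n_c)
    b = (msi - msg) / 2.0
    c = msg
    return a, b, c


def dxy_per_site(pA: float, pB: float) -> float:
    return pA * (1.0 - pB) + (1.0 - pA) * pB


def sfs_brute_force(dosage: np.ndarray, folded: bool = True) -> np.ndarray:
    """Per-site minor/derived allele counting by explicit loops."""
    n_samples, n_sites = dosage.shape
    counts = []
    for s in range(n_sites):
        col = dosage[:, s]
        obs = col[col >= 0]
        alt = int(obs.sum())
        n = 2 * len(obs)
        if alt == 0 or alt == n:
            continue
        counts.append(min(alt, n - alt) if folded else alt)
    return np.asarray(counts, dtype=int)
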