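"""Relative and absolute differentiation between two population groups.

Implements the Weir & Cockerham (1984) variance-components F_ST estimator
(per site and as a ratio-of-sums over sites or windows), windowed absolute
divergence D_XY, genome-wide and per-window permutation tests with an
empirical-p convention that never reports zero, Benjamini-Hochberg FDR
across windows, and the "genomic differentiation" (GD) classifier: GD holds
when significantly differentiated windows make up a vast majority (> 90% by
default) of untruncated windows.

The F_ST estimator decomposes allele-frequency variance into among-population
(a), among-individual-within-population (b), and within-individual (c)
components computed from genotype counts (including observed heterozygosity);
the multi-site estimate is sum(a) / sum(a+b+c), the "weighted" convention
used by the standard VCF tooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._util import rng_from
from .variants_io import GenotypeMatrix, WindowSpec, make_windows

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------


def _group_site_stats(dosage: np.ndarray, labels: np.ndarray):
    """Per-(labeling, site) genotyped count, alt frequency, het proportion.

    ``labels`` is a (B, n_samples) 0/1 indicator matrix selecting group
    members for B labelings at once; returns (n, p, h) each of shape (B, S).
    """
    obs = (dosage >= 0).astype(np.float64)
    alt = np.where(dosage > 0, dosage, 0).astype(np.float64)
    het = (dosage == 1).astype(np.float64)
    L = labels.astype(np.float64)
    n = L @ obs
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (L @ alt) / (2.0 * n)
        h = (L @ het) / n
    return n, p, h


def _wc_components(nA, pA, hA, nB, pB, hB):
    """WC84 a, b, c per site for two populations; invalid sites -> NaN.

    Sites are counted only when both groups have >= 2 genotyped samples.
    Monomorphic sites yield a = b = c = 0 and therefore contribute nothing
    to a ratio of sums.
    """
    valid = (nA >= 2) & (nB >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ntot = nA + nB
        nbar = ntot / 2.0
        nc = ntot - (nA**2 + nB**2) / ntot  # r - 1 == 1
        pbar = (nA * pA + nB * pB) / ntot
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / nbar  # / (r-1)
        hbar = (nA * hA + nB * hB) / ntot
        pq = pbar * (1.0 - pbar)
        a = (nbar / nc) * (s2 - (pq - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pq - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    bad = ~valid
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_site_components(gm: GenotypeMatrix, samplesA, samplesB):
    """Per-site WC84 (a, b, c) arrays for two sample groups."""
    idxA, idxB = gm.sample_indices(samplesA), gm.sample_indices(samplesB)
    n_samp = gm.n_samples
    LA = np.zeros((1, n_samp))
    LB = np.zeros((1, n_samp))
    LA[0, idxA] = 1.0
    LB[0, idxB] = 1.0
    nA, pA, hA = _group_site_stats(gm.dosage, LA)
    nB, pB, hB = _group_site_stats(gm.dosage, LB)
    a, b, c = _wc_components(nA, pA, hA, nB, pB, hB)
    return a[0], b[0], c[0]


def _ratio_of_sums(a, abc, axis=-1):
    num = np.nansum(a, axis=axis)
    den = np.nansum(abc, axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(den > 0, out, np.nan)


def wc_fst(gm: GenotypeMatrix, samplesA, samplesB, windows: pd.DataFrame | None = None):
    """Weir-Cockerham F_ST, genome-wide or per window.

    With ``windows=None`` returns the scalar ratio-of-sums estimate over all
    sites. With a window table (from :func:`make_windows`) returns the table
    with ``n_snps`` and ``fst`` columns added; windows without informative
    sites report NaN.
    """
    a, b, c = wc_site_components(gm, samplesA, samplesB)
    if not np.any(np.isfinite(a)):
        raise ValueError("no site has >= 2 genotyped samples in both groups")
    abc = a + b + c
    if windows is None:
        return float(_ratio_of_sums(a, abc))
    out = windows.copy()
    n_snps, fst = [], []
    for sites in _window_site_indices(gm, windows):
        n_snps.append(len(sites))
        fst.append(_ratio_of_sums(a[sites], abc[sites]) if len(sites) else np.nan)
    out["n_snps"] = n_snps
    out["fst"] = np.asarray(fst, dtype=float)
    return out


def _window_site_indices(gm: GenotypeMatrix, windows: pd.DataFrame):
    """Yield per-window global variant index arrays (0-based window coords)."""
    pos0 = gm.variants["pos"].to_numpy() - 1
    chrom = gm.variants["chrom"].to_numpy()
    offsets = {}
    for c in pd.unique(chrom):
        mask = chrom == c
        offsets[c] = (np.flatnonzero(mask), pos0[mask])
    for row in windows.itertuples(index=False):
        if row.chrom not in offsets:
            yield np.empty(0, dtype=int)
            continue
        gidx, p = offsets[row.chrom]
        lo, hi = np.searchsorted(p, [row.start, row.end])
        yield gidx[lo:hi]


# ---------------------------------------------------------------------------
# D_XY
# ---------------------------------------------------------------------------


def window_dxy(
    gm: GenotypeMatrix,
    samplesA,
    samplesB,
    windows: pd.DataFrame | WindowSpec,
) -> pd.DataFrame:
    """Absolute divergence per window.

    D_XY = sum over variant sites of ``pA (1-pB) + (1-pA) pB`` divided by the
    window length in bp; positions without a variant record are assumed
    invariant and contribute only to the denominator.
    """
    if isinstance(windows, WindowSpec):
        windows = make_windows(gm.chrom_lengths, windows)
    if not len(samplesA) or not len(samplesB):
        raise ValueError("both groups must be non-empty")
    pA = gm.alt_freq(gm.sample_indices(samplesA))
    pB = gm.alt_freq(gm.sample_indices(samplesB))
    per_site = pA * (1.0 - pB) + (1.0 - pA) * pB
    out = windows.copy()
    vals, n_snps = [], []
    for row, sites in zip(
        windows.itertuples(index=False), _window_site_indices(gm, windows)
    ):
        length = row.end - row.start
        vals.append(np.nansum(per_site[sites]) / length)
        n_snps.append(len(sites))
    out["n_snps"] = n_snps
    out["dxy"] = np.asarray(vals, dtype=float)
    return out


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    """Observed statistic, permutation null values, and empirical p-value.

    The empirical p uses the add-one convention
    ``p = (1 + #{null >= observed}) / (1 + B)`` so that an observed value
    exceeding every null replicate yields p = 1/(B+1), never zero.
    """

    observed: float
    null_values: np.ndarray
    p_empirical: float = field(init=False)

    def __post_init__(self) -> None:
        b = len(self.null_values)
        k = int(np.sum(np.asarray(self.null_values) >= self.observed))
        self.p_empirical = (1 + k) / (1 + b)


def _batched_fst(dosage, label_matrix):
    """Genome-wide WC F_ST for each row of a (B, n_samples) 0/1 label matrix."""
    nA, pA, hA = _group_site_stats(dosage, label_matrix)
    nB, pB, hB = _group_site_stats(dosage, 1 - label_matrix)
    a, b, c = _wc_components(nA, pA, hA, nB, pB, hB)
    return _ratio_of_sums(a, a + b + c, axis=1)


def _random_labelings(n_samples: int, nA: int, B: int, rng) -> np.ndarray:
    labels = np.zeros((B, n_samples), dtype=np.int8)
    base = np.arange(n_samples)
    for i in range(B):
        pick = rng.permutation(base)[:nA]
        labels[i, pick] = 1
    return labels


def permutation_test(
    gm: GenotypeMatrix,
    samplesA,
    samplesB,
    B: int = 100,
    seed: int | None = None,
) -> PermutationResult:
    """Random-grouping test of genome-wide F_ST.

    Sample labels are reshuffled B times preserving group sizes; the
    genome-wide WC F_ST is recomputed for each relabeling.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    from math import comb

    idxA = gm.sample_indices(samplesA)
    idxB = gm.sample_indices(samplesB)
    pool = np.concatenate([idxA, idxB])
    if comb(len(pool), len(idxA)) < B:
        logger.warning(
            "B=%d exceeds the number of distinct relabelings; duplicates retained", B
        )
    dosage = gm.dosage[pool]
    obs_labels = np.zeros((1, len(pool)), dtype=np.int8)
    obs_labels[0, : len(idxA)] = 1
    observed = float(_batched_fst(dosage, obs_labels)[0])
    rng = rng_from(seed)
    labels = _random_labelings(len(pool), len(idxA), B, rng)
    null = _batched_fst(dosage, labels)
    return PermutationResult(observed=observed, null_values=null)


def window_significance(
    gm: GenotypeMatrix,
    samplesA,
    samplesB,
    windows: pd.DataFrame | WindowSpec,
    B_window: int = 199,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-window permutation p-values for window F_ST, BH-corrected.

    Labels are permuted within each window (preserving group sizes) and the
    window's ratio-of-sums F_ST recomputed; Benjamini-Hochberg correction is
    applied across untruncated windows with data. Zero-SNP (or otherwise
    uninformative) windows are excluded from the FDR family and logged.
    """
    if B_window < 19:
        raise ValueError("B_window must be >= 19")
    if isinstance(windows, WindowSpec):
        windows = make_windows(gm.chrom_lengths, windows)
    idxA = gm.sample_indices(samplesA)
    idxB = gm.sample_indices(samplesB)
    pool = np.concatenate([idxA, idxB])
    rng = rng_from(seed)
    out = wc_fst(gm, samplesA, samplesB, windows=windows)
    pvals = np.full(len(out), np.nan)
    obs_labels = np.zeros((1, len(pool)), dtype=np.int8)
    obs_labels[0, : len(idxA)] = 1
    labels = _random_labelings(len(pool), len(idxA), B_window, rng)
    for w, sites in enumerate(_window_site_indices(gm, windows)):
        if len(sites) == 0 or not np.isfinite(out["fst"].iat[w]):
            continue
        dos = gm.dosage[np.ix_(pool, sites)]
        obs = out["fst"].iat[w]
        null = _batched_fst(dos, labels)
        k = int(np.nansum(null >= obs))
        pvals[w] = (1 + k) / (1 + B_window)
    out["p_value"] = pvals
    family = out["truncated"].to_numpy() == False  # noqa: E712
    family &= np.isfinite(pvals)
    n_dropped = int(((~np.isfinite(pvals)) & (out["truncated"].to_numpy() == False)).sum())  # noqa: E712
    if n_dropped:
        logger.info("%d windows without informative sites excluded from FDR", n_dropped)
    qvals = np.full(len(out), np.nan)
    if family.any():
        qvals[family] = multipletests(pvals[family], method="fdr_bh")[1]
    out["q_value"] = qvals
    out["significant"] = qvals < alpha
    return out


# ---------------------------------------------------------------------------
# Genomic differentiation (GD) and region reports
# ---------------------------------------------------------------------------


@dataclass
class GDReport:
    """Fractions of untruncated windows with positive / significant F_ST."""

    frac_positive: float
    frac_significant: float
    gd_flag: bool
    n_windows: int


def gd_classify(
    windowstats: pd.DataFrame, alpha: float = 0.05, threshold: float = 0.90
) -> GDReport:
    """Classify genomic differentiation: significant windows must exceed
    ``threshold`` (strictly) of untruncated windows with data."""
    w = windowstats
    if "truncated" in w.columns:
        w = w.loc[~w["truncated"].astype(bool)]
    w = w.loc[np.isfinite(w["fst"])]
    if not len(w):
        raise ValueError("no untruncated window with data")
    frac_positive = float((w["fst"] > 0).mean())
    if "q_value" in w.columns and np.isfinite(w["q_value"]).any():
        wq = w.loc[np.isfinite(w["q_value"])]
        frac_significant = float((wq["q_value"] < alpha).mean())
    else:
        frac_significant = float("nan")
    gd_flag = bool(frac_significant > threshold)
    return GDReport(frac_positive, frac_significant, gd_flag, len(w))


def region_report(
    windowstats: pd.DataFrame, chrom: str, start: int, end: int, stat: str = "fst"
) -> dict:
    """Percentile rank of a region's mean statistic within its chromosome.

    The region mean is taken over overlapping windows; the percentile is the
    fraction of the chromosome's windows with a value <= the region mean,
    scaled to 0..100.
    """
    cw = windowstats.loc[windowstats["chrom"] == chrom]
    cw = cw.loc[np.isfinite(cw[stat])]
    if not len(cw):
        raise ValueError(f"no windows with data on chromosome {chrom!r}")
    overlap = cw.loc[(cw["start"] < end) & (cw["end"] > start)]
    if not len(overlap):
        raise ValueError("region overlaps no window")
    region_mean = float(overlap[stat].mean())
    values = cw[stat].to_numpy()
    percentile = 100.0 * float(np.mean(values <= region_mean))
    return {
        "chrom": chrom,
        "start": start,
        "end": end,
        "stat": stat,
        "region_mean": region_mean,
        "chrom_mean": float(values.mean()),
        "chrom_median": float(np.median(values)),
        "n_windows": int(len(cw)),
        "percentile": percentile,
    }
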