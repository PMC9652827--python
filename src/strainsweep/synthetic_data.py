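"""Synthetic data generation: forward simulation, fixtures, sequence evolution.

Three generators live here:

* :func:`simulate_divergence` — a forward Wright-Fisher simulator of two
  sister populations splitting from a common ancestor, with unidirectional
  gene flow from Pop B into Pop A, single-locus divergent viability selection
  in Pop A, infinite-sites mutation, and Poisson crossover recombination.
  Population-scaled parameters (N s, N m, N mu L, N r L) are preserved under
  the ``rescale_q`` speed-up, so summaries of windowed differentiation are
  invariant to the rescaling up to sampling noise.
* :func:`make_structured_fixture` — fast Balding-Nichols genotype fixtures
  with a target F_ST and optional planted F1 hybrids, used to exercise the
  structure / differentiation machinery with known truth labels.
* :func:`simulate_f84_sequences` — sequence evolution under the F84
  substitution model along an arbitrary tree, the counterpart of the
  F84-distance estimator used for mitochondrial strain assignment.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy.linalg import expm

from ._util import rng_from
from .variants_io import GenotypeMatrix, SampleMetadata, WindowSpec, make_windows

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Two-population divergence model parameters (pre-rescaling).

    Defaults follow the validation model of the study system: human-like
    per-bp rates, diploid effective size 3100 per population, migration
    0.001 from Pop B into Pop A, selection coefficient 0.05 on a focal site
    in the middle of a 2 Mb sequence.

    ``rescale_q`` divides the population size and multiplies the per-bp
    rates and the selection/migration coefficients by the same factor, so
    the population-scaled products N*s, N*m, N*mu*L and N*r*L are invariant;
    generation counts (burn-in, post-split) are specified on the rescaled
    clock and default to 10*N' and 4*N'.
    """

    n_diploid: int = 3100
    mu: float = 1.2e-8
    rec: float = 1.19e-8
    mig: float = 0.001
    sel: float = 0.05
    dominance: float = 0.5
    seq_len: int = 2_000_000
    focal_pos: int | None = None  # None -> seq_len // 2
    burnin_gens: int | None = None  # None -> 10 * N_rescaled
    split_gens: int | None = None  # None -> N_rescaled // 4 (see below)
    rescale_q: float = 1.0
    seed: int = 0
    n_sample: int = 40  # haploid sample size per population at output

    def __post_init__(self) -> None:
        for name in ("mu", "rec", "mig"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be a rate in [0, 1]")
        if not np.isfinite(self.sel) or self.sel < 0:
            raise ValueError("sel must be finite and >= 0")
        if self.rescale_q < 1:
            raise ValueError("rescale_q must be >= 1")
        if self.seq_len <= 0 or self.n_diploid < 2:
            raise ValueError("seq_len must be > 0 and n_diploid >= 2")
        if self.focal_pos is None:
            self.focal_pos = self.seq_len // 2
        if not 0 <= self.focal_pos < self.seq_len:
            raise ValueError("focal_pos must lie in [0, seq_len)")

    def rescaled(self) -> SimpleNamespace:
        q = self.rescale_q
        N = max(2, int(round(self.n_diploid / q)))
        burnin = self.burnin_gens if self.burnin_gens is not None else 10 * N
        # post-split duration defaults to N/4 generations: long enough for
        # the selected allele to establish and fix and for migration to
        # differentially homogenize neutral background, short enough that
        # the sweep's frequency-spectrum footprint is still present at
        # sampling time (it decays on a ~N/2 timescale)
        split = self.split_gens if self.split_gens is not None else max(10, N // 4)
        return SimpleNamespace(
            N=N,
            mu_gam=self.mu * q * self.seq_len,  # new mutations per gamete
            R=self.rec * q * self.seq_len,  # crossovers per meiosis
            m=min(self.mig * q, 1.0),
            s=self.sel * q,
            h=self.dominance,
            L=self.seq_len,
            focal=self.focal_pos,
            burnin=burnin,
            split=split,
            n_sample=self.n_sample,
        )


@dataclass
class SimResult:
    """Replicate genotype matrices plus replicate-averaged window statistics."""

    config: SimulationConfig
    genotypes: list[GenotypeMatrix]
    windows: pd.DataFrame  # chrom/start/end of the window tiling
    fst_reps: np.ndarray  # (n_reps, n_windows)
    dxy_reps: np.ndarray
    n_reps: int
    reseed_counts: list[int] = field(default_factory=list)

    @property
    def fst_mean(self) -> np.ndarray:
        return np.nanmean(self.fst_reps, axis=0)

    @property
    def dxy_mean(self) -> np.ndarray:
        return np.nanmean(self.dxy_reps, axis=0)

    def focal_window_index(self) -> int:
        w = self.windows
        hit = (w["start"] <= self.config.focal_pos) & (self.config.focal_pos < w["end"])
        return int(np.flatnonzero(hit.to_numpy())[0])


# ---------------------------------------------------------------------------
# Core Wright-Fisher machinery
# ---------------------------------------------------------------------------


def _gametes(H, pos, parent_idx, R, L, rng):
    """One recombinant gamete per entry of ``parent_idx`` (individual index)."""
    G = len(parent_idx)
    S = H.shape[1]
    start = rng.integers(0, 2, G)
    if S == 0:
        return np.zeros((G, 0), dtype=np.uint8)
    k = rng.poisson(R, G)
    # start from the chosen haplotype; crossover gametes get segments of the
    # homolog copied over between successive crossover breakpoints
    out = H[2 * parent_idx + start]
    which = np.flatnonzero(k > 0)
    if len(which):
        kx = k[which].astype(np.int64)
        xpos = rng.uniform(0.0, L, int(kx.sum()))
        cuts = np.searchsorted(pos, xpos).astype(np.int64)
        starts = np.zeros(len(which), dtype=np.int64)
        starts[1:] = np.cumsum(kx)[:-1]
        other_row = (2 * parent_idx[which] + (1 - start[which])).astype(np.int64)
        _copy_segments(out, H, which.astype(np.int64), other_row, cuts, starts, kx)
    return out


def _copy_segments_py(out, H, which, other_row, cuts, starts, counts):
    S = out.shape[1]
    for i in range(len(which)):
        b = np.sort(cuts[starts[i] : starts[i] + counts[i]])
        other = H[other_row[i]]
        row = out[which[i]]
        for seg in range(0, len(b), 2):
            hi = b[seg + 1] if seg + 1 < len(b) else S
            row[b[seg] : hi] = other[b[seg] : hi]


try:  # numba accelerates the per-gamete segment copies ~10x
    from numba import njit

    _copy_segments = njit(cache=True)(_copy_segments_py)
except Exception:  # pragma: no cover
    _copy_segments = _copy_segments_py


def _offspring(H, pos, p1, p2, R, L, rng):
    """Diploid offspring rows (interleaved gametes) for parent index arrays."""
    g1 = _gametes(H, pos, p1, R, L, rng)
    g2 = _gametes(H, pos, p2, R, L, rng)
    out = np.empty((2 * len(p1), H.shape[1]), dtype=np.uint8)
    out[0::2] = g1
    out[1::2] = g2
    return out


def _mutate_and_prune(H, pos, mu_gam, L, rng, protect: int | None = None):
    """Add infinite-sites mutations, drop globally fixed/lost columns, sort."""
    rows = H.shape[0]
    n_mut = rng.poisson(rows * mu_gam)
    if n_mut:
        new_pos = rng.integers(0, L, n_mut)
        new_pos.sort()
        # drop duplicates among draws and collisions with existing sites
        dup = np.zeros(n_mut, dtype=bool)
        dup[1:] = new_pos[1:] == new_pos[:-1]
        ins = np.searchsorted(pos, new_pos)
        hit = np.zeros(n_mut, dtype=bool)
        inb = ins < len(pos)
        hit[inb] = pos[ins[inb]] == new_pos[inb]
        new_pos = new_pos[~(dup | hit)]
        block = np.zeros((rows, len(new_pos)), dtype=np.uint8)
        block[rng.integers(0, rows, len(new_pos)), np.arange(len(new_pos))] = 1
        H = np.concatenate([H, block], axis=1)
        pos = np.concatenate([pos, new_pos])
    colsum = H.sum(axis=0, dtype=np.int64)
    keep = (colsum > 0) & (colsum < rows)
    if protect is not None:
        keep |= pos == protect
    kept = np.flatnonzero(keep)
    take = kept[np.argsort(pos[kept], kind="stable")]
    return H[:, take], pos[take]


def _focal_column(pos, focal):
    j = np.searchsorted(pos, focal)
    if j < len(pos) and pos[j] == focal:
        return int(j)
    return None


def _insert_focal(H, pos, focal, carrier_row, rng):
    """Insert the selected allele at ``focal`` carried by one haplotype."""
    j = _focal_column(pos, focal)
    if j is not None:  # collision with a neutral site: overwrite it
        H[:, j] = 0
        H[carrier_row, j] = 1
        return H, pos
    j = int(np.searchsorted(pos, focal))
    col = np.zeros((H.shape[0], 1), dtype=np.uint8)
    col[carrier_row, 0] = 1
    H = np.concatenate([H[:, :j], col, H[:, j:]], axis=1)
    pos = np.concatenate([pos[:j], [focal], pos[j:]])
    return H, pos


def _simulate_one(cfg: SimulationConfig, seed: int):
    """Run one replicate; returns (hapA, hapB, pos, n_reseeds)."""
    p = cfg.rescaled()
    rng = np.random.default_rng(seed)
    N = p.N
    H = np.zeros((2 * N, 0), dtype=np.uint8)
    pos = np.empty(0, dtype=np.int64)

    # burn-in: single ancestral population, neutral
    for _ in range(p.burnin):
        par = rng.integers(0, N, (2, N))
        H = _offspring(H, pos, par[0], par[1], p.R, p.L, rng)
        H, pos = _mutate_and_prune(H, pos, p.mu_gam, p.L, rng)

    # split: found Pop A and Pop B from the ancestral gene pool
    par = rng.integers(0, N, (4, N))
    H = np.concatenate(
        [
            _offspring(H, pos, par[0], par[1], p.R, p.L, rng),
            _offspring(H, pos, par[2], par[3], p.R, p.L, rng),
        ],
        axis=0,
    )
    n_reseeds = 0
    selected = p.s > 0
    if selected:
        H, pos = _insert_focal(H, pos, p.focal, rng.integers(0, 2 * N), rng)

    rows_A = slice(0, 2 * N)
    for _ in range(p.split):
        # Pop A parents: fitness-weighted by focal dosage; migrants from B
        if selected:
            j = _focal_column(pos, p.focal)
            dosage_A = H[rows_A, j].reshape(N, 2).sum(axis=1)
            w = 1.0 + np.where(dosage_A == 2, p.s, 0.0) + np.where(
                dosage_A == 1, p.h * p.s, 0.0
            )
            probs = w / w.sum()
        else:
            probs = None
        parA1 = rng.choice(N, N, p=probs)
        parA2 = rng.choice(N, N, p=probs)
        # unidirectional migration B -> A: migrant offspring take B parents
        mig_mask = rng.random(N) < p.m
        n_mig = int(mig_mask.sum())
        if n_mig:
            parA1[mig_mask] = N + rng.integers(0, N, n_mig)
            parA2[mig_mask] = N + rng.integers(0, N, n_mig)
        parB1 = N + rng.integers(0, N, N)
        parB2 = N + rng.integers(0, N, N)
        H = _offspring(
            H,
            pos,
            np.concatenate([parA1, parB1]),
            np.concatenate([parA2, parB2]),
            p.R,
            p.L,
            rng,
        )
        H, pos = _mutate_and_prune(
            H, pos, p.mu_gam, p.L, rng, protect=p.focal if selected else None
        )
        if selected:
            j = _focal_column(pos, p.focal)
            lost = j is None or H[rows_A, j].sum() == 0
            if lost:
                H, pos = _insert_focal(H, pos, p.focal, rng.integers(0, 2 * N), rng)
                n_reseeds += 1
        # drop an all-zero protected focal column in Pop B context is handled
        # by the keep-mask on the next generation once re-seeded
    if n_reseeds:
        logger.info("selected allele re-seeded %d time(s)", n_reseeds)

    take = min(p.n_sample, 2 * N)
    idxA = rng.choice(2 * N, take, replace=False)
    idxB = 2 * N + rng.choice(2 * N, take, replace=False)
    return H[idxA], H[idxB], pos, n_reseeds


def _genotypes_from_haplotypes(hapA, hapB, pos, seq_len, chrom="sim1"):
    """Pair consecutive haplotypes into diploids and build a GenotypeMatrix."""
    nA = hapA.shape[0] // 2
    nB = hapB.shape[0] // 2
    dosA = hapA[: 2 * nA].reshape(nA, 2, hapA.shape[1]).sum(axis=1)
    dosB = hapB[: 2 * nB].reshape(nB, 2, hapB.shape[1]).sum(axis=1)
    dosage = np.concatenate([dosA, dosB], axis=0).astype(np.int8)
    # keep only sites segregating in the pooled sample
    tot = dosage.sum(axis=0)
    seg = (tot > 0) & (tot < 2 * (nA + nB))
    dosage = dosage[:, seg]
    kept = pos[seg]
    samples = [f"A{i:03d}" for i in range(nA)] + [f"B{i:03d}" for i in range(nB)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": kept + 1,
            "ref": "A",
            "alt": "T",
        }
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": samples,
                "group": ["popA"] * nA + ["popB"] * nB,
            }
        )
    )
    gm = GenotypeMatrix(
        samples=samples,
        variants=variants,
        dosage=dosage,
        chrom_lengths={chrom: seq_len},
    )
    return gm, meta


def simulate_divergence(
    config: SimulationConfig,
    n_reps: int = 50,
    window_bp: int = 20_000,
) -> SimResult:
    """Run the two-population divergence model and summarize per window.

    Each replicate r uses seed ``config.seed + r``. Windowed F_ST and D_XY
    are computed with the differentiation estimators on the sampled diploid
    genotypes and averaged over replicates (NaN where a window has no
    informative site in a replicate).
    """
    from .differentiation import wc_fst, window_dxy

    windows = make_windows(
        {"sim1": config.seq_len}, WindowSpec(size_bp=window_bp, untruncated_only=False)
    )
    fst_reps = np.full((n_reps, len(windows)), np.nan)
    dxy_reps = np.full((n_reps, len(windows)), np.nan)
    genotypes: list[GenotypeMatrix] = []
    reseeds: list[int] = []
    for r in range(n_reps):
        hapA, hapB, pos, n_res = _simulate_one(config, config.seed + r)
        gm, meta = _genotypes_from_haplotypes(hapA, hapB, pos, config.seq_len)
        genotypes.append(gm)
        reseeds.append(n_res)
        gA = meta.group_samples("popA")
        gB = meta.group_samples("popB")
        if gm.n_variants:
            try:
                fst_reps[r] = wc_fst(gm, gA, gB, windows=windows)["fst"].to_numpy()
            except ValueError:
                pass
            dxy_reps[r] = window_dxy(gm, gA, gB, windows)["dxy"].to_numpy()
    return SimResult(
        config=config,
        genotypes=genotypes,
        windows=windows,
        fst_reps=fst_reps,
        dxy_reps=dxy_reps,
        n_reps=n_reps,
        reseed_counts=reseeds,
    )


def sample_diversity(gm: GenotypeMatrix, samples=None) -> float:
    """Mean pairwise nucleotide diversity per site (unbiased, per bp)."""
    idx = None if samples is None else gm.sample_indices(samples)
    d = gm.dosage if idx is None else gm.dosage[idx]
    obs = d >= 0
    n_hap = 2 * obs.sum(axis=0)
    alt = np.where(obs, d, 0).sum(axis=0)
    ok = n_hap > 1
    p = alt[ok] / n_hap[ok]
    het = 2.0 * p * (1.0 - p) * n_hap[ok] / (n_hap[ok] - 1.0)
    length = sum(gm.chrom_lengths.values())
    return float(het.sum() / length)


# ---------------------------------------------------------------------------
# Structured genotype fixtures (Balding-Nichols divergence model)
# ---------------------------------------------------------------------------


def make_structured_fixture(
    n_per_group: int,
    n_variants: int,
    fst_target: float,
    n_hybrids: int = 0,
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
    z_chroms: set[str] | None = None,
) -> tuple[GenotypeMatrix, SampleMetadata]:
    """Two-population genotype fixture with a target Weir-Cockerham F_ST.

    Per-population allele frequencies are drawn from the Balding-Nichols
    model ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around an ancestral frequency
    p ~ U(0.1, 0.9) with F = ``fst_target`` (F = 0 means shared frequencies,
    i.e. panmixia). Hybrid samples receive one allele from each population's
    frequency pool at every locus, the F1 expectation. Truth labels are
    returned as metadata (group popA/popB/hybrid, ``is_hybrid`` flag).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0 <= fst_target <= 0.95:
        raise ValueError("fst_target must be in [0, 0.95]")
    rng = rng_from(seed)
    p_anc = rng.uniform(0.1, 0.9, n_variants)
    if fst_target == 0:
        pA = pB = p_anc
    else:
        F = fst_target
        shape = (1.0 - F) / F
        pA = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        pB = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        eps = 1e-6
        pA = np.clip(pA, eps, 1 - eps)
        pB = np.clip(pB, eps, 1 - eps)
    gA = rng.binomial(2, pA, size=(n_per_group, n_variants))
    gB = rng.binomial(2, pB, size=(n_per_group, n_variants))
    gH = rng.binomial(1, pA, size=(n_hybrids, n_variants)) + rng.binomial(
        1, pB, size=(n_hybrids, n_variants)
    )
    dosage = np.concatenate([gA, gB, gH], axis=0).astype(np.int8)
    samples = (
        [f"A{i:03d}" for i in range(n_per_group)]
        + [f"B{i:03d}" for i in range(n_per_group)]
        + [f"H{i:03d}" for i in range(n_hybrids)]
    )
    groups = ["popA"] * n_per_group + ["popB"] * n_per_group + ["hybrid"] * n_hybrids
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 100 * (n_variants + 1)}
    variants = _spread_positions(n_variants, chrom_lengths)
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": samples,
                "group": groups,
                "is_hybrid": [g == "hybrid" for g in groups],
            }
        )
    )
    gm = GenotypeMatrix(
        samples=samples,
        variants=variants,
        dosage=dosage,
        chrom_lengths=dict(chrom_lengths),
        z_chroms=set(z_chroms or ()),
    )
    return gm, meta


def _spread_positions(n_variants: int, chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Deterministically spread variants across chromosomes pro rata."""
    total = sum(chrom_lengths.values())
    rows = []
    remaining = n_variants
    items = list(chrom_lengths.items())
    for i, (chrom, length) in enumerate(items):
        k = remaining if i == len(items) - 1 else round(n_variants * length / total)
        k = min(k, remaining)
        step = max(1, length // (k + 1))
        pos = (np.arange(1, k + 1) * step)[:k]
        pos = pos[pos <= length]
        for p in pos:
            rows.append((chrom, int(p)))
        remaining -= len(pos)
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    df["ref"] = "A"
    df["alt"] = "G"
    return df


def make_demo_dataset(
    seed: int = 0,
    n_per_group: int = 12,
    n_variants: int = 3000,
    fst_target: float = 0.2,
    n_hybrids: int = 1,
    n_discordant: int = 3,
) -> dict:
    """Bundled end-to-end demo: genotypes, metadata, markers, truth labels.

    Two host-plant groups (popA ~ corn / C strain, popB ~ grass / R strain)
    over three autosomes plus a Z chromosome, a diagnostic TPI-like locus on
    the Z where the strains are near-fixed for alternative alleles, and
    COX1-like mitochondrial sequences (two haplogroup clades plus labeled
    references). ``n_discordant`` popA samples carry the R mitotype,
    mimicking the mito-nuclear discordance seen in real collections.
    """
    rng = rng_from(seed)
    chrom_lengths = {
        "chr1": 1_200_000,
        "chr2": 1_000_000,
        "chr3": 800_000,
        "chrZ": 900_000,
    }
    gm, meta = make_structured_fixture(
        n_per_group,
        n_variants,
        fst_target,
        n_hybrids=n_hybrids,
        seed=seed,
        chrom_lengths=chrom_lengths,
        z_chroms={"chrZ"},
    )
    # diagnostic TPI-like locus: strains near-fixed for alternative alleles
    tpi_locus = ("chrZ", 100_000, 160_000)
    v = gm.variants
    in_locus = (
        (v["chrom"] == "chrZ").to_numpy()
        & (v["pos"].to_numpy() - 1 >= tpi_locus[1])
        & (v["pos"].to_numpy() - 1 < tpi_locus[2])
    )
    idx = np.flatnonzero(in_locus)
    groups = meta.table["group"].to_numpy()
    for j in idx:
        pa, pb = 0.03, 0.97
        for i, g in enumerate(groups):
            if g == "popA":
                gm.dosage[i, j] = rng.binomial(2, pa)
            elif g == "popB":
                gm.dosage[i, j] = rng.binomial(2, pb)
            else:  # hybrid: one allele from each strain background
                gm.dosage[i, j] = rng.binomial(1, pa) + rng.binomial(1, pb)
    # truth labels: nuclear strain C for popA, R for popB
    tpi_truth = np.where(groups == "popA", "C", "R")
    tpi_truth = np.where(groups == "hybrid", "ambiguous", tpi_truth)
    cox1_truth = np.where(groups == "popA", "C", "R").astype(object)
    a_idx = np.flatnonzero(groups == "popA")
    for i in a_idx[:n_discordant]:
        cox1_truth[i] = "R"
    tbl = meta.table.copy()
    tbl["host_plant"] = np.select(
        [groups == "popA", groups == "popB"], ["corn", "grass"], default="corn"
    )
    tbl["site"] = "demo"
    tbl["tpi_truth"] = tpi_truth
    tbl["cox1_truth"] = cox1_truth
    meta = SampleMetadata(tbl)
    # COX1-like haplogroups: two clades, labeled references in each
    refs = {"Cref1": "C", "Cref2": "C", "Rref1": "R", "Rref2": "R"}
    tipsC = ["Cref1", "Cref2"] + [
        s for s, c in zip(meta.table["sample_id"], cox1_truth) if c == "C"
    ]
    tipsR = ["Rref1", "Rref2"] + [
        s for s, c in zip(meta.table["sample_id"], cox1_truth) if c == "R"
    ]
    def clade(tips):
        return "(" + ",".join(f"{t}:{0.004}" for t in tips) + ")"
    newick = f"({clade(tipsC)}:0.12,{clade(tipsR)}:0.12);"
    seqs = simulate_f84_sequences(
        newick,
        base_freqs=(0.31, 0.17, 0.15, 0.37),
        ts_tv_ratio=2.5,
        seq_len=900,
        seed=int(rng.integers(2**31 - 1)),
    )
    cox1_refs = {k: seqs[k] for k in refs}
    cox1_queries = {
        s: seqs[s] for s in meta.table["sample_id"] if s in seqs
    }
    return {
        "gm": gm,
        "meta": meta,
        "tpi_locus": tpi_locus,
        "tpi_refs": {"A000": "C", "B000": "R"},
        "cox1_refs": cox1_refs,
        "cox1_ref_strains": refs,
        "cox1_queries": cox1_queries,
    }


# ---------------------------------------------------------------------------
# F84 sequence simulation
# ---------------------------------------------------------------------------

BASES = np.array(list("ACGT"))
_PURINE = np.array([True, False, True, False])


def f84_rate_matrix(base_freqs, ts_tv_ratio: float) -> np.ndarray:
    """F84 instantaneous rate matrix scaled to one expected sub/site/unit."""
    pi = np.asarray(base_freqs, dtype=float)
    if pi.shape != (4,) or abs(pi.sum() - 1.0) > 1e-8 or np.any(pi <= 0):
        raise ValueError("base_freqs must be 4 positive values summing to 1")
    piR = pi[0] + pi[2]
    piY = pi[1] + pi[3]
    A = pi[0] * pi[2] / piR + pi[1] * pi[3] / piY
    B = pi[0] * pi[2] + pi[1] * pi[3]
    C = piR * piY
    kappa = (ts_tv_ratio * C - B) / A
    if kappa < 0:
        raise ValueError("ts_tv_ratio too small for these base frequencies")
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = pi[j]
            if _PURINE[i] == _PURINE[j]:  # transition
                cls = piR if _PURINE[j] else piY
                rate *= 1.0 + kappa / cls
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(pi, np.diag(Q))
    return Q / scale


def _as_tree(tree):
    from skbio import TreeNode

    if isinstance(tree, TreeNode):
        return tree
    return TreeNode.read(io.StringIO(str(tree)))


def simulate_f84_sequences(
    tree,
    base_freqs=(0.25, 0.25, 0.25, 0.25),
    ts_tv_ratio: float = 2.0,
    seq_len: int = 1000,
    seed: int | None = None,
) -> dict[str, str]:
    """Evolve aligned sequences along ``tree`` under the F84 model.

    ``tree`` is a newick string or an skbio TreeNode with branch lengths in
    expected substitutions per site. Returns {tip name: sequence}.
    """
    if seq_len <= 0:
        raise ValueError("seq_len must be positive")
    root = _as_tree(tree)
    for node in root.traverse():
        if node.length is not None and node.length < 0:
            raise ValueError("branch lengths must be >= 0")
    Q = f84_rate_matrix(base_freqs, ts_tv_ratio)
    rng = rng_from(seed)
    pi = np.asarray(base_freqs, dtype=float)
    states = {id(root): rng.choice(4, size=seq_len, p=pi)}
    out: dict[str, str] = {}
    for node in root.preorder(include_self=True):
        if node is root:
            pass
        else:
            t = node.length or 0.0
            P = expm(Q * t) if t > 0 else np.eye(4)
            P = np.clip(P, 0, None)
            P /= P.sum(axis=1, keepdims=True)
            parent_state = states[id(node.parent)]
            u = rng.random(seq_len)
            cum = np.cumsum(P, axis=1)
            child = (u[:, None] > cum[parent_state]).sum(axis=1)
            states[id(node)] = child
        if node.is_tip():
            out[node.name] = "".join(BASES[states[id(node)]])
    return out
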