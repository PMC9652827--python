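"""Host-plant strain assignment from nuclear and mitochondrial markers.

Two independent marker systems are implemented:

* ``tpi_assign`` — nuclear assignment from a diagnostic Z-linked locus
  (TPI-like): PCA restricted to the locus's variants, a 2-means split on
  PC1, and cluster-to-strain mapping through reference samples of known
  strain. Samples close to the cluster midpoint are called ambiguous.
* ``cox1_assign`` — mitochondrial assignment from aligned COX1-like
  sequences: maximum-likelihood F84 distances to labeled reference
  sequences, nearest-reference calls with a distance margin, and a
  neighbor-joining tree over all sequences for reporting.

The F84 substitution model allows unequal base frequencies plus a
transition/transversion bias; its pairwise maximum-likelihood distance has
the closed form

    d = -2A log(1 - P/(2A) - (A-B) Q/(2AC)) + 2(A-B-C) log(1 - Q/(2C))

with P and Q the transition and transversion proportions and A, B, C
composition terms from the base frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import genotype_pca
from .variants_io import GenotypeMatrix

logger = logging.getLogger(__name__)

AMBIGUOUS = "ambiguous"


@dataclass
class StrainCall:
    sample_id: str
    tpi_strain: str | None = None
    cox1_strain: str | None = None
    evidence: float = float("nan")  # PC1 score or distance margin


# ---------------------------------------------------------------------------
# F84 distance
# ---------------------------------------------------------------------------

_PURINES = set("AG")
_VALID = set("ACGT")


class SaturationError(ValueError):
    """F84 distance undefined: substitution proportions beyond saturation."""


def _pair_counts(seqA: str, seqB: str):
    """(n compared, n transitions, n transversions, pooled base counts).

    Alignment columns with a gap or ambiguity code in either sequence are
    excluded pairwise.
    """
    if len(seqA) != len(seqB):
        raise ValueError("sequences must be aligned to equal length")
    a = np.frombuffer(seqA.upper().encode(), dtype="S1")
    b = np.frombuffer(seqB.upper().encode(), dtype="S1")
    codes = np.array([b"A", b"C", b"G", b"T"])
    ia = np.searchsorted(codes, a)
    ib = np.searchsorted(codes, b)
    ok_a = (ia < 4) & (codes[np.minimum(ia, 3)] == a)
    ok_b = (ib < 4) & (codes[np.minimum(ib, 3)] == b)
    ok = ok_a & ok_b
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable (gap-free) columns")
    ia, ib = ia[ok], ib[ok]
    diff = ia != ib
    purine_a = (ia == 0) | (ia == 2)
    purine_b = (ib == 0) | (ib == 2)
    transitions = int((diff & (purine_a == purine_b)).sum())
    transversions = int((diff & (purine_a != purine_b)).sum())
    freqs = (
        np.bincount(ia, minlength=4) + np.bincount(ib, minlength=4)
    ).astype(float)
    return n, transitions, transversions, freqs / freqs.sum()


def f84_distance(seqA: str, seqB: str, base_freqs=None) -> float:
    """Maximum-likelihood F84 distance in substitutions per site.

    Base frequencies default to the pooled empirical frequencies of the two
    sequences. Raises :class:`SaturationError` when a logarithm argument is
    non-positive (distance undefined).
    """
    n, ts, tv, emp = _pair_counts(seqA, seqB)
    pi = emp if base_freqs is None else np.asarray(base_freqs, dtype=float)
    if np.any(pi <= 0):
        # a base absent from both sequences: fall back to tiny pseudocount
        pi = np.maximum(pi, 1e-6)
        pi = pi / pi.sum()
    P, Q = ts / n, tv / n
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    A = piA * piG / piR + piC * piT / piY
    B = piA * piG + piC * piT
    C = piR * piY
    w1 = 1.0 - P / (2.0 * A) - (A - B) * Q / (2.0 * A * C)
    w2 = 1.0 - Q / (2.0 * C)
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"saturated sequence pair (P={P:.4f}, Q={Q:.4f}): distance undefined"
        )
    return float(-2.0 * A * np.log(w1) + 2.0 * (A - B - C) * np.log(w2))


def f84_distance_se(seqA: str, seqB: str, base_freqs=None) -> float:
    """Delta-method standard error of the F84 distance estimate."""
    n, ts, tv, emp = _pair_counts(seqA, seqB)
    pi = emp if base_freqs is None else np.asarray(base_freqs, dtype=float)
    P, Q = ts / n, tv / n
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    A = piA * piG / piR + piC * piT / piY
    B = piA * piG + piC * piT
    C = piR * piY
    w1 = 1.0 - P / (2.0 * A) - (A - B) * Q / (2.0 * A * C)
    w2 = 1.0 - Q / (2.0 * C)
    dP = 1.0 / w1
    dQ = (A - B) / (C * w1) - (A - B - C) / (C * w2)
    var = (dP**2 * P * (1 - P) + dQ**2 * Q * (1 - Q) - 2 * dP * dQ * P * Q) / n
    return float(np.sqrt(max(var, 0.0)))


def f84_distance_matrix(seqs: dict[str, str], base_freqs=None) -> pd.DataFrame:
    """Symmetric matrix of pairwise F84 distances (NaN where saturated)."""
    names = list(seqs)
    k = len(names)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            try:
                d[i, j] = d[j, i] = f84_distance(
                    seqs[names[i]], seqs[names[j]], base_freqs
                )
            except SaturationError:
                d[i, j] = d[j, i] = np.nan
    return pd.DataFrame(d, index=names, columns=names)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []  # list of (child, branch_length)


@dataclass
class Tree:
    """Unrooted tree from neighbor joining; lengths clamped at >= 0."""

    root: _Node
    taxa: list[str]

    def to_newick(self) -> str:
        def fmt(node, length=None):
            if node.children:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                s = f"({inner})"
            else:
                s = node.name
            return s if length is None else f"{s}:{length:.10g}"

        return fmt(self.root) + ";"

    def tip_distances(self) -> pd.DataFrame:
        """Pairwise path lengths between tips."""
        dists = {}

        def walk(node, acc):
            if not node.children:
                dists[node.name] = acc
                return
            for child, length in node.children:
                walk(child, acc + length)

        # path lengths via root paths (tree is connected & acyclic)
        paths = {}

        def collect(node, path):
            if not node.children:
                paths[node.name] = path
            for child, length in node.children:
                collect(child, path + [(id(node), length)])

        collect(self.root, [])
        names = self.taxa
        out = np.zeros((len(names), len(names)))
        # distance = sum of branch lengths on symmetric difference of paths
        full = {}

        def collect2(node, acc):
            for child, length in node.children:
                collect2(child, acc + [(id(child), length)])
                if not child.children:
                    full[child.name] = acc + [(id(child), length)]

        collect2(self.root, [])
        for i, a in enumerate(names):
            ea = dict(full[a])
            for j in range(i + 1, len(names)):
                eb = dict(full[names[j]])
                shared = set(ea) & set(eb)
                d = sum(l for k, l in ea.items() if k not in shared) + sum(
                    l for k, l in eb.items() if k not in shared
                )
                out[i, j] = out[j, i] = d
        return pd.DataFrame(out, index=names, columns=names)


def neighbor_joining(dist: pd.DataFrame) -> Tree:
    """Saitou-Nei neighbor joining with the rate-corrected Q criterion.

    Ties break deterministically on the lowest taxon-index pair. Negative
    branch-length estimates are clamped to zero (pre-clamp values logged).
    """
    names = list(dist.index)
    D = dist.to_numpy(dtype=float).copy()
    if D.shape[0] != D.shape[1] or len(names) < 3:
        raise ValueError("need a square matrix over >= 3 taxa")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("matrix must be symmetric with zero diagonal")
    nodes = [_Node(name=n) for n in names]
    active = list(range(len(names)))
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Qm = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Qm, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Qm), Qm.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        ai, aj = active[i_], active[j_]
        dij = D[ai, aj]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = dij - li
        for name, val in (("left", li), ("right", lj)):
            if val < 0:
                logger.info("NJ %s branch estimate %.3g clamped to 0", name, val)
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = _Node(children=[(nodes[ai], li), (nodes[aj], lj)])
        # distances from the new node to remaining taxa
        newd = 0.5 * (D[ai] + D[aj] - dij)
        D = np.vstack([D, newd])
        newd2 = np.append(newd, 0.0)
        D = np.hstack([D, newd2[:, None]])
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]
    a, b = active
    mid = max(D[a, b], 0.0)
    root = _Node(children=[(nodes[a], mid / 2.0), (nodes[b], mid / 2.0)])
    return Tree(root=root, taxa=names)


# ---------------------------------------------------------------------------
# Assignment operations
# ---------------------------------------------------------------------------


def tpi_assign(
    gm: GenotypeMatrix,
    locus: tuple[str, int, int],
    reference_labels: dict[str, str],
    ambiguous_frac: float = 0.5,
) -> pd.DataFrame:
    """Strain assignment from a diagnostic nuclear locus.

    ``locus`` is (chrom, start, end) in 0-based half-open coordinates;
    ``reference_labels`` maps at least one sample per strain to its known
    label. PCA is computed from the locus's variants only, samples are split
    by 2-means on PC1, clusters inherit the strain labels of their reference
    members, and samples within ``ambiguous_frac`` pooled-within-cluster
    standard deviations of the cluster midpoint are called ambiguous.
    """
    chrom, start, end = locus
    v = gm.variants
    mask = (
        (v["chrom"] == chrom).to_numpy()
        & (v["pos"].to_numpy() - 1 >= start)
        & (v["pos"].to_numpy() - 1 < end)
    )
    sub = gm.subset_variants(mask)
    poly = np.array(
        [len(np.unique(col[col >= 0])) > 1 for col in sub.dosage.T], dtype=bool
    )
    if poly.sum() < 3:
        raise ValueError("locus contains fewer than 3 polymorphic variants")
    pca = genotype_pca(sub.subset_variants(poly), n_components=1)
    pc1 = pca.coordinates[:, 0]
    labels, centers = _two_means_1d(pc1)
    strains = _map_clusters(gm.samples, labels, reference_labels)
    midpoint = centers.mean()
    sd = _pooled_sd(pc1, labels)
    calls = []
    for s, score, lab in zip(gm.samples, pc1, labels):
        strain = strains[lab]
        if abs(score - midpoint) <= ambiguous_frac * sd:
            strain = AMBIGUOUS
        calls.append((s, strain, float(score)))
    return pd.DataFrame(calls, columns=["sample_id", "tpi_strain", "evidence"])


def _two_means_1d(x: np.ndarray, max_iter: int = 100):
    c = np.array([x.min(), x.max()], dtype=float)
    if c[0] == c[1]:
        raise ValueError("degenerate scores: locus not diagnostic")
    for _ in range(max_iter):
        labels = (np.abs(x - c[0]) > np.abs(x - c[1])).astype(int)
        new = np.array([x[labels == k].mean() if np.any(labels == k) else c[k] for k in (0, 1)])
        if np.allclose(new, c):
            break
        c = new
    return labels, c


def _pooled_sd(x, labels) -> float:
    devs = [x[labels == k] - x[labels == k].mean() for k in (0, 1) if np.any(labels == k)]
    dev = np.concatenate(devs)
    return float(np.sqrt(np.mean(dev**2)))


def _map_clusters(samples, labels, reference_labels) -> dict[int, str]:
    by_cluster: dict[int, set[str]] = {0: set(), 1: set()}
    idx = {s: i for i, s in enumerate(samples)}
    for ref, strain in reference_labels.items():
        if ref not in idx:
            raise KeyError(f"reference sample {ref!r} not in matrix")
        by_cluster[labels[idx[ref]]].add(strain)
    if by_cluster[0] & by_cluster[1] or not (by_cluster[0] and by_cluster[1]):
        raise ValueError(
            "reference samples do not separate into distinct clusters: "
            "locus not diagnostic"
        )
    return {k: next(iter(v)) for k, v in by_cluster.items()}


def cox1_assign(
    queries: dict[str, str],
    references: dict[str, str],
    reference_strains: dict[str, str],
    epsilon: float = 1e-6,
    base_freqs=None,
) -> tuple[pd.DataFrame, Tree]:
    """Mitochondrial strain assignment by nearest F84 reference.

    Each query is assigned the strain of its nearest reference; the margin
    is the gap to the nearest reference of any *other* strain, and calls
    with margin < ``epsilon`` (or saturation against all references) are
    ambiguous. A neighbor-joining tree over all sequences is returned for
    reporting alongside the calls.
    """
    if not queries or not references:
        raise ValueError("need at least one query and one reference")
    strains = set(reference_strains.values())
    if len(strains) < 2:
        raise ValueError("need references from >= 2 strains")
    rows = []
    for qname, qseq in queries.items():
        dists: dict[str, float] = {}
        for rname, rseq in references.items():
            try:
                dists[rname] = f84_distance(qseq, rseq, base_freqs)
            except SaturationError:
                continue
        if not dists:
            logger.warning("query %s saturated against all references", qname)
            rows.append((qname, AMBIGUOUS, float("nan")))
            continue
        best_ref = min(dists, key=dists.get)
        best_strain = reference_strains[best_ref]
        others = [
            d for r, d in dists.items() if reference_strains[r] != best_strain
        ]
        margin = (min(others) - dists[best_ref]) if others else float("inf")
        call = AMBIGUOUS if margin < epsilon else best_strain
        rows.append((qname, call, float(margin)))
    calls = pd.DataFrame(rows, columns=["sample_id", "cox1_strain", "evidence"])
    allseq = {**references, **queries}
    dm = f84_distance_matrix(allseq, base_freqs)
    if dm.isna().any().any():
        # saturated pairs have undefined distances; cap them so the report
        # tree can still be built (the assignment itself never uses the cap)
        cap = 1.5 * np.nanmax(dm.to_numpy())
        logger.warning("saturated pairs in tree matrix capped at %.3g", cap)
        dm = dm.fillna(cap)
    tree = neighbor_joining(dm)
    return calls, tree


def combine_calls(
    tpi: pd.DataFrame | None, cox1: pd.DataFrame | None
) -> pd.DataFrame:
    """Merge marker-specific calls into one StrainCall table."""
    frames = []
    if tpi is not None:
        frames.append(tpi.set_index("sample_id")[["tpi_strain"]])
    if cox1 is not None:
        frames.append(cox1.set_index("sample_id")[["cox1_strain"]])
    if not frames:
        raise ValueError("no calls to combine")
    out = pd.concat(frames, axis=1).reset_index()
    return out.rename(columns={"index": "sample_id"})
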