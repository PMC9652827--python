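"""VCF / metadata I/O, the genotype-matrix data model, hard filters, windows.

The in-memory container is :class:`GenotypeMatrix`: an ordered samples x
biallelic-SNV matrix of alternate-allele dosages (0/1/2, -1 for missing).
Coordinates are stored 1-based as in VCF; all window arithmetic is done on
0-based half-open intervals and converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: GATK-style hard-filter thresholds for SNVs. A record is discarded iff any
#: annotation violates its bound strictly; a missing annotation never triggers
#: its clause.
HARD_FILTER_THRESHOLDS = {
    "QD": ("<", 2.0),
    "FS": (">", 60.0),
    "MQ": ("<", 40.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
}


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNV alternate-allele dosage matrix.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (rows of ``dosage``).
    variants : pandas.DataFrame
        Columns ``chrom, pos, ref, alt``; ``pos`` is 1-based. Positions are
        strictly increasing within each chromosome.
    dosage : ndarray of int8, shape (n_samples, n_variants)
        Count of alternate alleles per genotype; ``-1`` marks missing.
    chrom_lengths : dict
        Chromosome name -> length in bp.
    z_chroms : set of str
        Chromosome names treated as Z-linked.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    z_chroms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.dosage.size and (self.dosage.max() > 2 or self.dosage.min() < -1):
            raise ValueError("dosage entries must be in {-1, 0, 1, 2}")
        pos = self.variants["pos"].to_numpy()
        chrom = self.variants["chrom"].to_numpy()
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample {e.args[0]!r}") from None

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return replace(
            self,
            variants=self.variants.loc[mask].reset_index(drop=True),
            dosage=self.dosage[:, mask],
        )

    def subset_samples(self, names) -> "GenotypeMatrix":
        idx = self.sample_indices(names)
        return replace(self, samples=list(names), dosage=self.dosage[idx])

    def alt_freq(self, sample_idx=None) -> np.ndarray:
        """Observed alternate-allele frequency per variant (missing excluded)."""
        d = self.dosage if sample_idx is None else self.dosage[sample_idx]
        obs = d >= 0
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)


@dataclass
class SampleMetadata:
    """Per-sample annotations: group, host plant, site, optional strain labels."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "group")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        self.table = self.table.reset_index(drop=True)

    def covers(self, samples) -> bool:
        return set(samples) <= set(self.table["sample_id"])

    def group_samples(self, group) -> list[str]:
        t = self.table
        return t.loc[t["group"] == group, "sample_id"].tolist()

    @classmethod
    def read_tsv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class WindowSpec:
    """Genomic window definition: fixed size, optional smaller step (sliding)."""

    size_bp: int = 500_000
    step_bp: int | None = None  # None -> non-overlapping (step == size)
    untruncated_only: bool = False

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValueError("size_bp must be positive")
        if self.step_bp is not None and not 0 < self.step_bp <= self.size_bp:
            raise ValueError("step_bp must be in (0, size_bp]")

    @property
    def step(self) -> int:
        return self.size_bp if self.step_bp is None else self.step_bp


def make_windows(chrom_lengths: dict[str, int], spec: WindowSpec) -> pd.DataFrame:
    """Tile each chromosome with half-open windows ``[start, start+size)``.

    Returns a DataFrame with 0-based half-open ``start``/``end`` plus a
    ``truncated`` flag; truncated windows (extending past the chromosome end)
    are dropped when ``spec.untruncated_only`` and clipped otherwise.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        for start in range(0, length, spec.step):
            end = start + spec.size_bp
            truncated = end > length
            if truncated and spec.untruncated_only:
                continue
            if start >= length:  # pragma: no cover
                break
            rows.append((chrom, start, min(end, length), truncated))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "truncated"])


def windows_to_bed(windows: pd.DataFrame, path) -> None:
    windows[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def partition_z_autosome(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Split variants into the Z-linked subset and the autosomal subset."""
    chrom = gm.variants["chrom"].to_numpy()
    is_z = np.isin(chrom, sorted(gm.z_chroms))
    if gm.z_chroms and not is_z.any():
        logger.warning("z_chroms %s name no chromosome in the matrix", gm.z_chroms)
    return gm.subset_variants(is_z), gm.subset_variants(~is_z)


def hard_filter(annotations: pd.DataFrame) -> np.ndarray:
    """Boolean keep-mask applying the SNV hard filters.

    ``annotations`` holds one row per record with any subset of the columns
    QD, FS, MQ, MQRankSum, ReadPosRankSum; NaN/absent values never trigger
    their clause, and values exactly at a threshold are retained (the bounds
    are strict).
    """
    discard = np.zeros(len(annotations), dtype=bool)
    for name, (op, thr) in HARD_FILTER_THRESHOLDS.items():
        if name not in annotations.columns:
            continue
        vals = pd.to_numeric(annotations[name], errors="coerce").to_numpy(float)
        with np.errstate(invalid="ignore"):
            bad = (vals < thr) if op == "<" else (vals > thr)
        discard |= np.nan_to_num(bad, nan=False).astype(bool) & ~np.isnan(vals)
    return ~discard


def read_vcf(
    path,
    metadata_path=None,
    z_chroms: set[str] | None = None,
) -> tuple[GenotypeMatrix, SampleMetadata | None]:
    """Load a VCF into a :class:`GenotypeMatrix` (+ metadata if given).

    Only biallelic SNVs are kept; multiallelic or non-SNV records are skipped
    with a logged count. Half-calls and ``./.`` genotypes become missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        dos = np.full(len(samples), MISSING, dtype=np.int8)
        for i, g in enumerate(rec.genotypes):
            a = g[:-1]  # last element is phasing flag
            if len(a) == 2 and a[0] >= 0 and a[1] >= 0:
                dos[i] = a[0] + a[1]
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(dos)
    if n_skipped:
        logger.info("skipped %d multiallelic/non-SNV records", n_skipped)
    lengths = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}
    variants = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosage = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        samples=samples,
        variants=variants,
        dosage=dosage,
        chrom_lengths=lengths,
        z_chroms=set(z_chroms or ()),
    )
    gm.n_skipped_records = n_skipped
    meta = None
    if metadata_path is not None:
        meta = SampleMetadata.read_tsv(metadata_path)
        missing = set(samples) - set(meta.table["sample_id"])
        if missing:
            raise ValueError(f"samples absent from metadata: {sorted(missing)}")
    return gm, meta


_GT = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix as a minimal VCF v4.2 with GT genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=strainsweep\n")
        for chrom, length in gm.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        v = gm.variants
        for j in range(gm.n_variants):
            gts = "\t".join(_GT[int(d)] for d in gm.dosage[:, j])
            fh.write(
                f"{v.chrom.iat[j]}\t{v.pos.iat[j]}\t.\t{v.ref.iat[j]}\t"
                f"{v.alt.iat[j]}\t.\t.\t.\tGT\t{gts}\n"
            )
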