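"""End-to-end orchestration: strain ID -> structure -> differentiation ->
GD -> sweep scan -> signature classification, from a single configuration.

Each stage gets an independent seed derived from the global seed by stable
hashing of the stage name, so results are reproducible stage-by-stage and
independent of execution order. All statistic tables are written as TSV
with fixed float formatting, so identical configurations produce
byte-identical outputs; the JSON manifest additionally records wall-clock
timings and row counts per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differentiation as diff
from . import strain_id as sid
from . import structure as struct
from . import sweep_scan as sw
from ._util import stage_seed
from .variants_io import GenotypeMatrix, SampleMetadata, WindowSpec, read_vcf

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.8g"


@dataclass
class RunConfig:
    """Inputs, thresholds, and seeds for a full analysis run."""

    out_dir: str = "strainsweep_run"
    vcf: str | None = None
    metadata: str | None = None
    cox1_fasta: str | None = None
    cox1_ref_strains: dict = field(default_factory=dict)  # ref seq name -> strain
    tpi_locus: tuple | None = None  # (chrom, start, end), 0-based half-open
    tpi_refs: dict = field(default_factory=dict)  # sample -> strain
    demo: bool = False  # run on the bundled synthetic demo dataset
    window_bp: int = 500_000
    dxy_step_bp: int = 100_000
    permutation_B: int = 100
    window_B: int = 199
    alpha: float = 0.05
    gd_threshold: float = 0.90
    hybrid_lo: float = 0.35
    hybrid_hi: float = 0.65
    outlier_z: float = 6.0
    sweep_grid_n: int = 1000
    sweep_folded: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if cfg.tpi_locus is not None:
            cfg.tpi_locus = tuple(cfg.tpi_locus)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def validate(self) -> None:
        if not self.demo and (self.vcf is None or self.metadata is None):
            raise ValueError("need vcf+metadata paths unless demo=True")
        for name in ("alpha", "gd_threshold", "hybrid_lo", "hybrid_hi"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.permutation_B < 1 or self.window_B < 19:
            raise ValueError("permutation counts too small")
        for p in (self.vcf, self.metadata, self.cox1_fasta):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path {p} does not exist")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_full(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }

    def record(stage: str, t0: float, **info):
        manifest["stages"].append(
            {"stage": stage, "seconds": round(time.time() - t0, 3), **info}
        )

    # ---- inputs -----------------------------------------------------------
    t0 = time.time()
    if config.demo:
        from .synthetic_data import make_demo_dataset

        demo = make_demo_dataset(seed=stage_seed(config.seed, "demo-data"))
        gm, meta = demo["gm"], demo["meta"]
        cox1_queries = demo["cox1_queries"]
        cox1_refs = demo["cox1_refs"]
        cox1_ref_strains = demo["cox1_ref_strains"]
        tpi_locus, tpi_refs = demo["tpi_locus"], demo["tpi_refs"]
    else:
        gm, meta = read_vcf(config.vcf, config.metadata)
        tpi_locus, tpi_refs = config.tpi_locus, config.tpi_refs
        cox1_queries, cox1_refs, cox1_ref_strains = {}, {}, {}
        if config.cox1_fasta:
            seqs = _read_fasta(config.cox1_fasta)
            cox1_ref_strains = dict(config.cox1_ref_strains)
            cox1_refs = {k: seqs[k] for k in cox1_ref_strains}
            cox1_queries = {k: v for k, v in seqs.items() if k not in cox1_refs}
    groups = sorted(g for g in meta.table["group"].unique() if g != "hybrid")
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 non-hybrid groups, got {groups}")
    gA = meta.group_samples(groups[0])
    gB = meta.group_samples(groups[1])
    record("load", t0, n_samples=gm.n_samples, n_variants=gm.n_variants)

    try:
        # ---- stage 1: strain identification --------------------------------
        t0 = time.time()
        tpi_calls = cox1_calls = None
        if tpi_locus is not None:
            tpi_calls = sid.tpi_assign(gm, tpi_locus, tpi_refs)
        if cox1_queries:
            cox1_calls, tree = sid.cox1_assign(
                cox1_queries, cox1_refs, cox1_ref_strains
            )
            (out / "cox1_tree.nwk").write_text(tree.to_newick() + "\n")
        if tpi_calls is not None or cox1_calls is not None:
            calls = sid.combine_calls(tpi_calls, cox1_calls)
            _write_tsv(calls, out / "strain_calls.tsv")
            table1 = summarize_table1(calls, meta)
            _write_tsv(table1.reset_index(), out / "table1.tsv")
        record("strain_id", t0, n_calls=0 if tpi_calls is None else len(tpi_calls))

        # ---- stage 2: structure --------------------------------------------
        t0 = time.time()
        pca = struct.genotype_pca(gm, n_components=10)
        pca_df = pd.DataFrame(
            pca.coordinates,
            columns=[f"PC{i+1}" for i in range(pca.coordinates.shape[1])],
        )
        pca_df.insert(0, "sample_id", gm.samples)
        _write_tsv(pca_df, out / "pca.tsv")
        anc = struct.ancestry_coefficients(
            gm, K=2, seed=stage_seed(config.seed, "ancestry")
        )
        hyb = struct.hybrid_flag(anc, config.hybrid_lo, config.hybrid_hi)
        q_df = pd.DataFrame(anc.Q, columns=["Q1", "Q2"])
        q_df.insert(0, "sample_id", gm.samples)
        q_df["hybrid_flag"] = hyb
        _write_tsv(q_df, out / "ancestry.tsv")
        record("structure", t0, n_hybrids=int(hyb.sum()))

        # ---- stage 3: differentiation --------------------------------------
        t0 = time.time()
        fst_genome = diff.wc_fst(gm, gA, gB)
        perm = diff.permutation_test(
            gm, gA, gB, B=config.permutation_B,
            seed=stage_seed(config.seed, "permutation"),
        )
        _write_tsv(
            pd.DataFrame({"null_fst": perm.null_values}), out / "permutation_null.tsv"
        )
        wspec = WindowSpec(size_bp=config.window_bp, untruncated_only=True)
        wstats = diff.window_significance(
            gm, gA, gB, wspec, B_window=config.window_B, alpha=config.alpha,
            seed=stage_seed(config.seed, "window-significance"),
        )
        dxy = diff.window_dxy(
            gm, gA, gB,
            WindowSpec(size_bp=config.window_bp, step_bp=config.dxy_step_bp),
        )
        _write_tsv(wstats, out / "fst_windows.tsv")
        _write_tsv(dxy, out / "dxy_windows.tsv")
        record(
            "differentiation", t0,
            fst=fst_genome, p_permutation=perm.p_empirical, n_windows=len(wstats),
        )

        # ---- stage 4: genomic differentiation ------------------------------
        t0 = time.time()
        gd = diff.gd_classify(wstats, alpha=config.alpha, threshold=config.gd_threshold)
        record(
            "gd", t0,
            frac_positive=gd.frac_positive,
            frac_significant=gd.frac_significant,
            gd_flag=gd.gd_flag,
        )

        # ---- stage 5: sweep scan -------------------------------------------
        t0 = time.time()
        scanA = sw.clr_scan(gm, gA, grid_n=config.sweep_grid_n, folded=config.sweep_folded)
        scanB = sw.clr_scan(gm, gB, grid_n=config.sweep_grid_n, folded=config.sweep_folded)
        _write_tsv(scanA.table, out / f"clr_{groups[0]}.tsv")
        _write_tsv(scanB.table, out / f"clr_{groups[1]}.tsv")
        outA = sw.group_specific_outliers(scanA, scanB, z_thresh=config.outlier_z)
        outB = sw.group_specific_outliers(scanB, scanA, z_thresh=config.outlier_z)
        _write_tsv(outA, out / f"outliers_{groups[0]}.tsv")
        _write_tsv(outB, out / f"outliers_{groups[1]}.tsv")
        record("sweep_scan", t0, n_outliers_A=len(outA), n_outliers_B=len(outB))

        # ---- stage 6: sweep signature --------------------------------------
        t0 = time.time()
        merged = wstats.merge(
            dxy[["chrom", "start", "end", "dxy"]], on=["chrom", "start", "end"],
            how="inner",
        )
        labels = []
        for which, table in (("A", outA), ("B", outB)):
            for _, row in table.iterrows():
                try:
                    lab = sw.sweep_signature(row, merged)
                except ValueError:
                    lab = "no-window"
                labels.append((which, row["chrom"], row["start"], row["end"], lab))
        sig = pd.DataFrame(
            labels, columns=["group", "chrom", "start", "end", "classification"]
        )
        _write_tsv(sig, out / "sweep_signatures.tsv")
        record("signature", t0, n_classified=len(sig))
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise
    manifest["n_stages_completed"] = len(manifest["stages"]) - 1  # minus load
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def summarize_table1(
    straincalls: pd.DataFrame, metadata: SampleMetadata
) -> pd.DataFrame:
    """Cross-tabulate strain calls by host plant, per marker.

    Mirrors the classic two-marker concordance table: counts of each strain
    call (including an ambiguous margin) within each host-plant class, for
    the nuclear (TPI) and mitochondrial (COX1) markers separately.
    """
    meta = metadata.table
    if "host_plant" not in meta.columns:
        meta = meta.assign(host_plant=meta["group"])
    merged = straincalls.merge(
        meta[["sample_id", "host_plant"]], on="sample_id", how="left"
    )
    if merged["host_plant"].isna().any():
        missing = merged.loc[merged["host_plant"].isna(), "sample_id"].tolist()
        raise ValueError(f"metadata does not cover samples: {missing}")
    blocks = []
    for marker in ("tpi_strain", "cox1_strain"):
        if marker not in merged.columns:
            continue
        col = merged[marker].fillna("ambiguous")
        tab = pd.crosstab(merged["host_plant"], col)
        tab.columns = [f"{marker.split('_')[0]}_{c}" for c in tab.columns]
        blocks.append(tab)
    if not blocks:
        raise ValueError("no marker columns present")
    out = pd.concat(blocks, axis=1).fillna(0).astype(int)
    out.index.name = "host_plant"
    return out
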