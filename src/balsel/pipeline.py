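"""Orchestration of the full balancing-selection scan.

Stage order mirrors the study design: tile-level theta map, beta scan with
MAF and indel filters, per-gene beta_std maxima, outlier call against the
control-gene 95th percentile, ML-HKA on the outliers, sliding-window
diversity tracks for outliers (with an automatic short-gene window preset),
LD blocks and a median-joining network for HKA-significant genes, and a
Mann-Whitney comparison of gene categories. Every stage logs counts in/out
so records surviving each filter are auditable; all randomness is seeded
from the config, and reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.stats import mannwhitneyu

from . import beta_scan as bs
from . import io_formats as iof
from . import ld_hap
from . import popgen_core as pg
from .hka import HKALocus, run_mlhka

__all__ = [
    "ScanConfig",
    "ScanReport",
    "run_scan",
    "scan_core",
    "mann_whitney_u",
    "category_compare",
]


@dataclass
class ScanConfig:
    """Paths, gene lists and stage parameters of one scan run."""

    vcf: Optional[str] = None
    gff: Optional[str] = None
    repeat_bed: Optional[str] = None
    gap_bed: Optional[str] = None
    indel_bed: Optional[str] = None
    neutral_loci: Optional[str] = None  # HKA panel TSV
    divergence: Optional[str] = None  # per-gene D counts TSV
    candidates: list[str] = field(default_factory=list)
    controls: list[str] = field(default_factory=list)
    categories: dict = field(default_factory=dict)  # gene -> "prm_evasion"|"other"
    window_bp: int = 2000
    maf_min: float = 0.15
    sharpness_p: float = 2.0
    indel_radius: int = 1000
    percentile_q: float = 95.0
    theta_tile: int = 10_000
    track_window: int = 2000
    track_step: int = 500
    short_window: int = 500
    short_step: int = 50
    short_gene_factor: float = 4.0  # short preset when gene length < factor * window
    network_region: Optional[tuple[int, int]] = None
    alpha: float = 0.05
    hka_all_genes: bool = False
    k_on_divergence: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat = {}
        for key, val in raw.items():
            if isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in flat.items() if k in known}
        if "network_region" in kwargs and kwargs["network_region"] is not None:
            kwargs["network_region"] = tuple(kwargs["network_region"])
        return cls(**kwargs)

    def beta_config(self) -> bs.BetaConfig:
        return bs.BetaConfig(
            window_bp=self.window_bp,
            maf_min=self.maf_min,
            sharpness_p=self.sharpness_p,
            indel_radius=self.indel_radius,
        )

    def digest(self) -> str:
        payload = {k: repr(v) for k, v in sorted(self.__dict__.items())}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ScanReport:
    gene_table: Optional[pd.DataFrame] = None
    diagnostics: Optional[pd.DataFrame] = None
    beta_track: Optional[pd.DataFrame] = None
    outliers: list = field(default_factory=list)
    hka_table: Optional[pd.DataFrame] = None
    tracks: dict = field(default_factory=dict)
    ld_pairs: dict = field(default_factory=dict)
    ld_blocks: dict = field(default_factory=dict)
    networks: dict = field(default_factory=dict)
    category_tests: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    log: list = field(default_factory=list)
    error: Optional[str] = None
    completed_stages: list = field(default_factory=list)


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact p by enumeration when min(n_a, n_b) <= 8 and no ties are present;
    otherwise the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CategoryTest:
    defined: bool
    n_a: int = 0
    n_b: int = 0
    median_a: float = float("nan")
    median_b: float = float("nan")
    U: float = float("nan")
    p: float = float("nan")


def _mwu_or_undefined(a, b) -> CategoryTest:
    if len(a) < 2 or len(b) < 2:
        return CategoryTest(defined=False, n_a=len(a), n_b=len(b))
    U, p = mann_whitney_u(a, b)
    return CategoryTest(
        defined=True,
        n_a=len(a),
        n_b=len(b),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        U=U,
        p=p,
    )


def category_compare(summaries, labels: dict) -> dict:
    """Mann-Whitney comparisons of gene-level beta_std_max.

    Two contrasts: candidates-of-balancing-selection vs other focal genes
    (labels "prm_evasion" vs "other"), and all focal genes vs controls
    (label "control"). Genes with missing maxima are excluded and counted.
    """
    vals = {
        s.gene_id: s.beta_std_max
        for s in summaries
        if np.isfinite(s.beta_std_max)
    }
    excluded = [s.gene_id for s in summaries if not np.isfinite(s.beta_std_max)]
    prm = [v for g, v in vals.items() if labels.get(g) == "prm_evasion"]
    other = [v for g, v in vals.items() if labels.get(g) == "other"]
    control = [v for g, v in vals.items() if labels.get(g) == "control"]
    focal = prm + other
    return {
        "prm_vs_other": _mwu_or_undefined(prm, other),
        "focal_vs_control": _mwu_or_undefined(focal, control),
        "n_excluded_missing": len(excluded),
        "excluded": excluded,
    }


def scan_core(
    variants,
    genes,
    masks,
    candidates: list[str],
    controls: list[str],
    cfg: ScanConfig,
    theta=None,
) -> tuple[pd.DataFrame, list, list, object]:
    """Theta map, beta scan and the per-gene outlier call (in-memory core).

    Returns (beta_track, candidate_summaries, control_summaries, theta_map).
    This is the code path :func:`run_scan` executes after loading its inputs.
    """
    if theta is None:
        theta = pg.theta_map(variants, masks, tile=cfg.theta_tile)
    track = bs.scan(variants, theta, masks, cfg.beta_config())
    by_id = {g.gene_id: g for g in genes}
    cand = [bs.gene_beta_max(by_id[g], track) for g in candidates]
    ctrl = [bs.gene_beta_max(by_id[g], track) for g in controls]
    cand = bs.outlier_call(cand, ctrl, q=cfg.percentile_q)
    return track, cand, ctrl, theta


def _load_hka_panel(path) -> list[HKALocus]:
    df = pd.read_csv(path, sep="\t")
    return [
        HKALocus(
            locus_id=str(r["locus_id"]),
            S=int(r["S"]),
            D=int(r["D"]),
            n=int(r["n"]),
            L=int(r.get("L", 0)),
            is_candidate=bool(r.get("is_candidate", False)),
        )
        for _, r in df.iterrows()
    ]


def run_scan(config: ScanConfig, out_dir: Optional[str] = None) -> ScanReport:
    """Execute the full scan; on stage failure, return completed stages plus
    a structured error (partial outputs retained)."""
    report = ScanReport()
    report.provenance = {"config_digest": config.digest(), "seed": config.seed}
    log = report.log
    try:
        stage = "load"
        variants = iof.read_vcf(config.vcf)
        genes = iof.read_gff(config.gff)
        masks = iof.read_masks(config.repeat_bed, config.gap_bed, config.indel_bed)
        log.append(f"load: {variants.load_report.summary()}; {len(genes)} genes")
        report.completed_stages.append(stage)

        stage = "theta_map"
        theta = pg.theta_map(variants, masks, tile=config.theta_tile)
        n_tiles = len(theta.tiles)
        n_missing = sum(
            1 for th, eff, _ in theta.tiles.values() if eff <= 0 or not np.isfinite(th)
        )
        log.append(f"theta_map: {n_tiles} tiles, {n_missing} flagged missing")
        report.completed_stages.append(stage)

        stage = "beta_scan"
        track, cand, ctrl, _ = scan_core(
            variants, genes, masks, config.candidates, config.controls, config,
            theta=theta,
        )
        report.beta_track = track
        n_masked = int(track["masked"].sum())
        log.append(f"beta_scan: {len(track)} SNPs scored, {n_masked} masked")
        report.completed_stages.append(stage)

        stage = "outliers"
        threshold = bs.control_threshold(ctrl, q=config.percentile_q)
        outliers = [c for c in cand if c.outlier]
        report.outliers = outliers
        log.append(
            f"outliers: control {config.percentile_q:g}th percentile = "
            f"{threshold:.4g}; {len(outliers)} of {len(cand)} candidates"
        )
        report.completed_stages.append(stage)

        stage = "hka"
        hka_rows = []
        panel = _load_hka_panel(config.neutral_loci) if config.neutral_loci else None
        div = (
            pd.read_csv(config.divergence, sep="\t").set_index("gene_id")
            if config.divergence
            else None
        )
        by_id = {g.gene_id: g for g in genes}
        hka_genes = (
            [c.gene_id for c in cand] if config.hka_all_genes
            else [c.gene_id for c in outliers]
        )
        H = variants.haplotypes()
        for gid in hka_genes:
            gene = by_id[gid]
            if panel is None or div is None or gid not in div.index:
                hka_rows.append({"gene": gid, "skip_reason": "no-hka-inputs"})
                continue
            cds_H = [H.slice_region(s, e) for s, e in gene.cds]
            S = sum(pg.seg_sites(h) for h in cds_H if h.n_sites)
            locus = HKALocus(
                locus_id=gid,
                S=int(S),
                D=int(div.loc[gid, "D"]),
                n=H.n_hap,
                L=int(div.loc[gid, "L"]),
                is_candidate=True,
            )
            res = run_mlhka(panel + [locus], gid, config.k_on_divergence)
            res["gene"] = gid
            res["skip_reason"] = ""
            hka_rows.append(res)
        n_tested = sum(1 for r in hka_rows if not r.get("skip_reason"))
        for r in hka_rows:
            if not r.get("skip_reason") and n_tested:
                r["p_bonferroni"] = min(1.0, r["p"] * n_tested)
        report.hka_table = pd.DataFrame(hka_rows)
        log.append(f"hka: {n_tested} genes tested, "
                   f"{len(hka_rows) - n_tested} skipped")
        report.completed_stages.append(stage)

        stage = "tracks"
        for c in outliers:
            gene = by_id[c.gene_id]
            if gene.length < config.short_gene_factor * config.track_window:
                size, step = config.short_window, config.short_step
            else:
                size, step = config.track_window, config.track_step
            report.tracks[c.gene_id] = pg.sliding_windows(
                H, gene.gene_span, masks, gene.contig, size, step
            )
        log.append(f"tracks: {len(report.tracks)} genes")
        report.completed_stages.append(stage)

        stage = "ld_networks"
        significant = [
            r["gene"]
            for r in hka_rows
            if not r.get("skip_reason") and r.get("p", 1.0) < config.alpha
        ]
        ld_cfg = ld_hap.LDBlockConfig(maf_min=config.maf_min)
        for gid in significant:
            gene = by_id[gid]
            sub = H.slice_region(*gene.gene_span)
            pairs = ld_hap.ld_pairs(sub, ld_cfg)
            n_used = (
                int(max(pairs["j"].max(), pairs["i"].max()) + 1) if len(pairs) else 0
            )
            blocks = ld_hap.gabriel_blocks(pairs, n_used, ld_cfg)
            report.ld_pairs[gid] = pairs
            report.ld_blocks[gid] = pd.DataFrame(
                [
                    {
                        "contig": gene.contig,
                        "start": int(pairs[pairs["i"] == i]["pos_a"].iloc[0]) if len(pairs) else 0,
                        "end": int(pairs[pairs["j"] == j]["pos_b"].iloc[0]) + 1 if len(pairs) else 0,
                        "i": i,
                        "j": j,
                    }
                    for i, j in blocks
                ],
                columns=["contig", "start", "end", "i", "j"],
            )
            region = config.network_region or gene.gene_span
            net_H = H.slice_region(*region)
            seqs = ["".join(map(str, row)) for row in net_H.matrix]
            report.networks[gid] = ld_hap.median_joining_network(seqs)
        log.append(f"ld_networks: {len(significant)} genes")
        report.completed_stages.append(stage)

        stage = "categories"
        labels = dict(config.categories)
        for g in config.controls:
            labels.setdefault(g, "control")
        report.category_tests = category_compare(cand + ctrl, labels)
        report.completed_stages.append(stage)

        stage = "tables"
        hka_by_gene = {
            r["gene"]: r for r in hka_rows if not r.get("skip_reason")
        }
        gene_rows, diag_rows = [], []
        for c in cand:
            gene = by_id[c.gene_id]
            sub = H.slice_region(*gene.gene_span)
            S = pg.seg_sites(sub) if sub.n_sites else 0
            eff = pg.effective_length(gene.gene_span, masks, gene.contig)
            pi = pg.nucleotide_diversity(sub, eff) if eff > 0 and sub.n_sites else 0.0
            h = hka_by_gene.get(c.gene_id, {})
            gene_rows.append(
                {
                    "gene": c.gene_id,
                    "cds_length": gene.cds_length,
                    "S": S,
                    "pi": pi,
                    "k": h.get("k_hat", float("nan")),
                    "p_mlhka": h.get("p", float("nan")),
                    "beta_std_max": c.beta_std_max,
                    "percentile_rank": c.percentile_rank,
                }
            )
            diag_rows.append(
                {
                    "gene": c.gene_id,
                    "n_snps_used": c.n_snps_used,
                    "outlier": c.outlier,
                    "skip_reason": (
                        ""
                        if c.n_snps_used
                        else "no-usable-snps"
                    ),
                }
            )
        report.gene_table = pd.DataFrame(gene_rows, columns=iof.GENE_TABLE_COLUMNS)
        report.diagnostics = pd.DataFrame(diag_rows)
        report.completed_stages.append(stage)

        if out_dir is not None:
            iof.write_tables(report, out_dir)
            with open(os.path.join(out_dir, "run_log.txt"), "w") as fh:
                fh.write(f"config: {report.provenance['config_digest']}\n")
                fh.write("\n".join(log) + "\n")
    except Exception as exc:  # structured failure: keep partial outputs
        report.error = f"stage {stage}: {exc}"
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            with open(os.path.join(out_dir, "run_log.txt"), "w") as fh:
                fh.write("\n".join(log + [report.error]) + "\n")
    return report
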