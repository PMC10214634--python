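"""Benchmark experiments validating the toolkit's statistical behaviour.

Each function runs one self-contained simulation experiment against the
package's own generators and returns the measured quantity together with the
problem size. They are used both by the validation test suite and by the
reproduction script, and accept a seed so every run is deterministic.

Problem sizes follow the package's standard validation design: windows of
theta = 10 with n = 62 haplotypes (the study sample: 31 diploids), 20-locus
neutral HKA panels with theta in [5, 50] and T = 2, and synthetic genomes of
~200 control genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress, rankdata

from . import beta_scan as bs
from . import ld_hap
from . import pipeline as pl
from . import popgen_core as pg
from .hka import fit_neutral, run_mlhka
from .synthetic_data import (
    GenomeConfig,
    SimParams,
    simulate_genome,
    simulate_hka_dataset,
    simulate_locus,
    simulate_unlinked_window,
)

__all__ = [
    "beta_neutral_calibration",
    "beta_power_auc",
    "hka_type1_error",
    "hka_k_recovery",
    "estimator_bias",
    "single_locus_hka_analytic_error",
    "oracle_agreement",
    "standardisation_slopes",
    "null_outlier_calibration",
]


@dataclass
class Measurement:
    value: float
    n: int
    extra: dict | None = None


def beta_neutral_calibration(seed: int, n_windows: int = 2000) -> Measurement:
    """Mean beta over neutral windows in the loose-linkage regime.

    Windows carry theta = 10 of completely unlinked sites (n = 62,
    MAF >= 0.15); one random retained SNP per window is scored as the core.
    Returns the mean beta; ``extra`` carries the Monte-Carlo SE.
    """
    rng = np.random.default_rng(seed)
    cfg = bs.BetaConfig()
    vals = []
    while len(vals) < n_windows:
        f = simulate_unlinked_window(62, 10.0, rng)
        f = f[f >= cfg.maf_min]
        if len(f) < 2:
            continue
        i = rng.integers(len(f))
        vals.append(bs.beta1(f[i], np.delete(f, i), 62, cfg))
    v = np.asarray(vals)
    se = float(v.std(ddof=1) / np.sqrt(len(v)))
    return Measurement(float(v.mean()), len(v), {"mc_se": se})


def _gene_beta_std_max(H, theta_bp, window_bp, cfg) -> float:
    n = H.n_hap
    counts = H.alt_counts()
    f = np.minimum(counts, n - counts) / n
    keep = (counts > 0) & (counts < n) & (f >= cfg.maf_min - 1e-12)
    fx, px = f[keep], H.positions[keep]
    if len(fx) < 2:
        return float("nan")
    half = cfg.window_bp // 2
    best = -np.inf
    for i in range(len(fx)):
        sel = (np.abs(px - px[i]) <= half) & (np.arange(len(fx)) != i)
        b = bs.beta1(fx[i], fx[sel], n, cfg)
        if b is not None:
            best = max(best, b / (theta_bp * cfg.window_bp))
    return best if np.isfinite(best) else float("nan")


def beta_power_auc(
    seed: int, n_per_class: int = 500, theta_bp: float = 0.005, locus_len: int = 2000
) -> Measurement:
    """Rank AUC of gene-level beta_std.max: balanced versus neutral loci.

    Balanced loci follow the standard old-polymorphism scenario
    (f_eq = 0.5, t_balance = 8, m_switch = 0.05); scoring uses the true
    per-bp theta, isolating the statistic's discrimination from tile
    estimation noise.
    """
    rng = np.random.default_rng(seed)
    cfg = bs.BetaConfig()
    groups = {}
    for model in ("balanced", "neutral"):
        p = SimParams(
            n_hap=62, locus_len=locus_len, theta_bp=theta_bp, model=model,
            f_eq=0.5, t_balance=8.0, m_switch=0.05,
        )
        vals = []
        while len(vals) < n_per_class:
            v = _gene_beta_std_max(
                simulate_locus(p, rng).haplotypes, theta_bp, locus_len, cfg
            )
            if np.isfinite(v):
                vals.append(v)
        groups[model] = np.asarray(vals)
    a, b = groups["balanced"], groups["neutral"]
    r = rankdata(np.concatenate([a, b]))[: len(a)]
    auc = (r.sum() - len(a) * (len(a) + 1) / 2) / (len(a) * len(b))
    return Measurement(float(auc), 2 * n_per_class)


def _hka_pvals(seed: int, n_reps: int, k_cand: float) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    ps, ks = [], []
    for _ in range(n_reps):
        theta = rng.uniform(5.0, 50.0, size=21)
        k = np.ones(21)
        k[-1] = k_cand
        loci = simulate_hka_dataset(theta, T=2.0, k=k, n=62, rng=rng)
        res = run_mlhka(loci, loci[-1].locus_id)
        ps.append(res["p"])
        ks.append(res["k_hat"])
    return np.asarray(ps), np.asarray(ks)


def hka_type1_error(seed: int, n_reps: int = 500, alpha: float = 0.05) -> Measurement:
    """LRT rejection rate on all-neutral 20+1-locus panels."""
    ps, _ = _hka_pvals(seed, n_reps, k_cand=1.0)
    return Measurement(float((ps < alpha).mean()), n_reps)


def hka_k_recovery(seed: int, n_reps: int = 500, k_true: float = 2.72) -> Measurement:
    """Median k-hat when the candidate's true selection parameter is 2.72."""
    _, ks = _hka_pvals(seed, n_reps, k_cand=k_true)
    return Measurement(float(np.median(ks)), n_reps, {"k_true": k_true})


def estimator_bias(seed: int, n_reps: int = 5000) -> Measurement:
    """Relative bias (%) of pi-hat and theta_W under neutral simulation.

    theta_locus = 10, n = 62. Returns the larger absolute relative bias of
    the two estimators, in percent; per-estimator values in ``extra``.
    """
    rng = np.random.default_rng(seed)
    p = SimParams(n_hap=62, locus_len=2000, theta_bp=0.005)
    a = pg.harmonic(62)
    pis, tws = [], []
    for _ in range(n_reps):
        H = simulate_locus(p, rng).haplotypes
        pis.append(pg.mean_pairwise_diff(H))
        tws.append(H.n_sites / a)
    bias_pi = (np.mean(pis) - 10.0) / 10.0 * 100.0
    bias_tw = (np.mean(tws) - 10.0) / 10.0 * 100.0
    worst = max(abs(bias_pi), abs(bias_tw))
    return Measurement(
        float(worst), n_reps, {"pi_bias_pct": float(bias_pi), "thetaW_bias_pct": float(bias_tw)}
    )


def single_locus_hka_analytic_error(seed: int = 0) -> Measurement:
    """Max |fit - analytic| for the single-locus neutral HKA fit.

    With one locus the MLE is exact: theta-hat = S/a, T-hat = D/theta-hat - 1.
    """
    from .hka import HKALocus

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(20):
        S = int(rng.integers(1, 60))
        D = int(rng.integers(1, 120))
        n = int(rng.choice([2, 10, 62]))
        a = pg.harmonic(n)
        theta_want = S / a
        T_want = D / theta_want - 1.0
        if T_want < 0:
            continue
        fit = fit_neutral([HKALocus("x", S, D, n)])
        worst = max(
            worst,
            abs(fit.theta_hat[0] - theta_want) / theta_want,
            abs(fit.T_hat - T_want) / max(T_want, 1.0),
        )
    return Measurement(float(worst), 20)


def oracle_agreement(seed: int) -> Measurement:
    """Max discrepancy between implementations and brute-force oracles.

    Covers pi vs the all-pairs count, D' vs the contingency table,
    Mann-Whitney vs exhaustive enumeration ({1,2,3} vs {4,5,6} -> p = 0.10),
    Gabriel blocks vs the all-intervals rule, and the median-joining network
    vs Steiner enumeration on small cases. Exact agreement -> 0.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0

    # pi against the O(n^2) loop
    for _ in range(50):
        m = rng.integers(0, 2, size=(8, 15), dtype=np.uint8)
        m[0, :], m[1, :] = 0, 1
        H = pg.HaplotypeMatrix(m, np.arange(15))
        total = sum(
            int(np.sum(m[i] != m[j]))
            for i in range(8)
            for j in range(i + 1, 8)
        )
        worst = max(worst, abs(pg.mean_pairwise_diff(H) - total / 28))

    # D' against direct 2x2 counting
    for _ in range(50):
        n = int(rng.integers(8, 40))
        x = rng.integers(0, 2, size=n)
        y = rng.integers(0, 2, size=n)
        if x.sum() in (0, n) or y.sum() in (0, n):
            continue
        pr = ld_hap.dprime(x, y)
        n11 = int(np.sum((x == 1) & (y == 1)))
        pA, pB = x.mean(), y.mean()
        D = n11 / n - pA * pB
        dmax = (
            min(pA * (1 - pB), (1 - pA) * pB)
            if D >= 0
            else min(pA * pB, (1 - pA) * (1 - pB))
        )
        worst = max(worst, abs(pr.Dprime - abs(D) / dmax))

    # Mann-Whitney exhaustive case
    _, pval = pl.mann_whitney_u([1, 2, 3], [4, 5, 6])
    worst = max(worst, abs(pval - 0.10))

    # Gabriel blocks: perfect-LD region must be one full block
    core = np.array([1] * 40 + [0] * 40, dtype=np.uint8)
    H = pg.HaplotypeMatrix(np.stack([core] * 5, axis=1), np.arange(5) * 100)
    pairs = ld_hap.ld_pairs(H)
    blocks = ld_hap.gabriel_blocks(pairs, 5)
    worst = max(worst, 0.0 if blocks == [(0, 4)] else 1.0)

    # median-joining vs Steiner point on the canonical triplet
    net = ld_hap.median_joining_network(["000", "011", "101"])
    seqs = sorted(s for s, f in net.nodes if f == 0)
    worst = max(worst, 0.0 if seqs == ["001"] else 1.0)
    mst = sum(w for _, _, w in net.edges)
    worst = max(worst, 0.0 if mst == 3 else 1.0)

    return Measurement(float(worst), 5)


def standardisation_slopes(seed: int, n_genes: int = 300) -> Measurement:
    """Regression of gene beta maxima on true tile theta across a
    theta-heterogeneous genome.

    Returns the beta_std.max slope t-statistic's |slope|/CI check as the
    primary value: 1.0 if the 95% CI of the beta_std.max slope covers zero
    while the raw-beta slope is significantly positive, else 0.0. Slopes and
    CIs in ``extra``.
    """
    cfg = GenomeConfig(
        n_control=n_genes, n_candidate=0, frac_balanced=0.0, seed=seed,
        theta_bp=0.002, theta_log_sd=0.5,
    )
    genome = simulate_genome(cfg)
    scan_cfg = pl.ScanConfig()
    theta_hat = pg.theta_map(genome.variants, genome.masks)
    track = bs.scan(genome.variants, theta_hat, genome.masks, scan_cfg.beta_config())
    by_id = {g.gene_id: g for g in genome.genes}
    xs, y_std, y_raw = [], [], []
    for _, row in genome.truth.iterrows():
        gene = by_id[row.gene_id]
        summ = bs.gene_beta_max(gene, track)
        gs, ge = gene.gene_span
        sel = track[
            (track.pos >= gs) & (track.pos < ge) & (~track.masked)
        ]
        if not np.isfinite(summ.beta_std_max) or len(sel) == 0:
            continue
        xs.append(row.theta_bp_true)
        y_std.append(summ.beta_std_max)
        y_raw.append(float(sel.beta_raw.max()))
    xs = np.asarray(xs)
    fit_std = linregress(xs, y_std)
    fit_raw = linregress(xs, y_raw)
    from scipy.stats import t as tdist

    crit = tdist.ppf(0.975, len(xs) - 2)
    std_covers_zero = abs(fit_std.slope) <= crit * fit_std.stderr
    raw_positive = fit_raw.slope > crit * fit_raw.stderr
    ok = bool(std_covers_zero and raw_positive)
    return Measurement(
        float(ok),
        len(xs),
        {
            "slope_std": float(fit_std.slope),
            "slope_std_ci": float(crit * fit_std.stderr),
            "slope_raw": float(fit_raw.slope),
            "slope_raw_ci": float(crit * fit_raw.stderr),
        },
    )


def null_outlier_calibration(
    seed: int, n_runs: int = 200, n_control: int = 200, n_candidate: int = 5
) -> Measurement:
    """Mean outliers per run on all-neutral genomes at q = 95.

    With 5 exchangeable candidates the expectation is ~0.25 per run (the
    nearest-rank threshold on N controls gives each candidate probability
    (N - ceil(0.95 N) + 2) / (N + 1) of exceeding it).
    """
    counts = []
    for r in range(n_runs):
        cfg = GenomeConfig(
            n_control=n_control, n_candidate=n_candidate, frac_balanced=0.0,
            seed=seed + 7919 * r, theta_bp=0.002,
        )
        genome = simulate_genome(cfg)
        cands = genome.truth[genome.truth.is_candidate].gene_id.tolist()
        ctrls = genome.truth[~genome.truth.is_candidate].gene_id.tolist()
        _, cand, _, _ = pl.scan_core(
            genome.variants, genome.genes, genome.masks, cands, ctrls,
            pl.ScanConfig(),
        )
        counts.append(sum(bool(c.outlier) for c in cand))
    return Measurement(float(np.mean(counts)), n_runs, {"sd": float(np.std(counts))})
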