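"""Folded beta allele-frequency-correlation scan with theta standardisation.

A SNP maintained by long-term balancing selection drags linked neutral
variants towards its own equilibrium frequency, so the folded frequencies of
neighbouring SNPs correlate with the core SNP's frequency. For a core SNP at
folded frequency x_core the statistic contrasts two estimators of the
window's mutation supply:

    theta_beta = sum_i s(x_i, x_core) / A(x_core)
    theta_W    = m / a'

where the sum runs over the other MAF-filtered SNPs in the window,
s(x, y) = (1 - |x - y| / 0.5)^p is the frequency-similarity kernel,
m is the neighbour count, and the normalisers run over the folded frequency
classes that survive the minor-allele-frequency floor:

    A(x_core) = sum_{k >= k_min} s(k/n, x_core) e(k),   a' = sum_{k >= k_min} e(k)

with e(k) = 1/k + 1/(n-k) for k < n/2 and e(n/2) = 2/n, the expected folded
site-frequency spectrum under neutrality. Restricting both normalisers to
the retained classes keeps E[beta] = 0 under neutrality after MAF filtering;
the core's own contribution is excluded from both estimators for the same
reason (its similarity is 1 by construction, not by chance).

beta_std divides beta by the expected window mutation supply
(tile theta per bp times the effective window length), making values
comparable across mutation-rate heterogeneity. Gene-level summaries take the
maximum beta_std over unmasked SNPs in the gene span, and outliers are
called against the empirical 95th percentile of a large control-gene set.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .popgen_core import HaplotypeMatrix, effective_length

__all__ = [
    "BetaConfig",
    "GeneBetaSummary",
    "folded_freq",
    "similarity",
    "beta1",
    "standardize",
    "scan",
    "mask_near_indels",
    "gene_beta_max",
    "outlier_call",
]


@dataclass(frozen=True)
class BetaConfig:
    window_bp: int = 2000  # total window width centred on the core SNP
    maf_min: float = 0.15
    sharpness_p: float = 2.0
    indel_radius: int = 1000

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.sharpness_p <= 0:
            raise ValueError("sharpness_p must be positive")


def folded_freq(alt_count: int, n: int) -> float:
    """Folded (minor-allele) frequency min(c, n-c)/n; monomorphic is an error."""
    if not 0 < alt_count < n:
        raise ValueError(f"monomorphic site (count {alt_count} of {n})")
    return min(alt_count, n - alt_count) / n


def similarity(x_i, x_core, p: float):
    """Frequency-similarity kernel s = (1 - |x_i - x_core| / 0.5)^p in [0, 1]."""
    return (1.0 - np.abs(np.asarray(x_i) - x_core) / 0.5) ** p


def _k_min(n: int, maf_min: float) -> int:
    return max(1, int(np.ceil(maf_min * n - 1e-9)))


@lru_cache(maxsize=None)
def _folded_classes(n: int, maf_min: float):
    """Retained folded classes k/n and their neutral SFS weights e(k)."""
    kmax = n // 2
    ks = np.arange(_k_min(n, maf_min), kmax + 1)
    e = 1.0 / ks + 1.0 / (n - ks)
    if n % 2 == 0 and len(ks) and ks[-1] == kmax:
        e[-1] = 2.0 / n  # the two fold halves coincide
    return ks / n, e


def beta1(
    core_x: float,
    neighbor_xs: Sequence[float],
    n: int,
    cfg: BetaConfig,
) -> Optional[float]:
    """Raw beta for one core SNP given its window neighbours' folded freqs.

    ``neighbor_xs`` are the MAF-filtered SNPs in the window around the core,
    excluding the core itself. Returns None when the window is empty after
    filtering (a flagged-missing result, not zero).
    """
    xs = np.asarray(neighbor_xs, dtype=float)
    if xs.size == 0:
        return None
    x_classes, e = _folded_classes(n, cfg.maf_min)
    A = float(np.sum(similarity(x_classes, core_x, cfg.sharpness_p) * e))
    a_trunc = float(e.sum())
    theta_beta = float(np.sum(similarity(xs, core_x, cfg.sharpness_p))) / A
    theta_w = xs.size / a_trunc
    return theta_beta - theta_w


def standardize(beta_raw: float, theta_tile: Optional[float], eff_window: float):
    """beta divided by the expected window mutation supply theta * L_eff.

    Returns (beta_std, reason): reason is None on success, or "no-theta" /
    "zero-eff-window" when the result must be masked.
    """
    if theta_tile is None or not np.isfinite(theta_tile) or theta_tile <= 0:
        return None, "no-theta"
    if eff_window <= 0:
        return None, "zero-eff-window"
    return beta_raw / (theta_tile * eff_window), None


def scan(
    variants,
    theta,
    masks,
    cfg: BetaConfig = BetaConfig(),
    contig: Optional[str] = None,
) -> pd.DataFrame:
    """Per-SNP beta scan over a contig.

    ``variants`` is a VariantTable or HaplotypeMatrix; ``theta`` a ThetaMap
    (or a float per-bp theta to apply everywhere, useful in simulations).
    Every SNP passing the MAF floor is scored as a core against the other
    retained SNPs within +-window_bp/2. Returns a BED-like frame with
    columns contig, pos (0-based), folded_freq, beta_raw, beta_std, masked,
    reason; SNPs near indels are then masked via :func:`mask_near_indels`.
    """
    if hasattr(variants, "haplotypes"):
        contig = contig or variants.contig
        H = variants.haplotypes()
    else:
        H = variants
        contig = contig or "NA"
    n = H.n_hap
    counts = H.alt_counts()
    poly = (counts > 0) & (counts < n)
    folded = np.minimum(counts, n - counts) / n
    keep = poly & (folded >= cfg.maf_min - 1e-12)
    pos = H.positions[keep]
    fx = folded[keep]
    m = len(pos)
    half = cfg.window_bp // 2
    df = pd.DataFrame(
        {
            "contig": contig,
            "pos": pos,
            "folded_freq": fx,
            "beta_raw": np.nan,
            "beta_std": np.nan,
            "masked": np.zeros(m, dtype=bool),
            "reason": "",
        }
    )
    if m == 0:
        return df

    # class-wise prefix sums make the window similarity sums O(m * classes)
    x_classes, e = _folded_classes(n, cfg.maf_min)
    n_cls = len(x_classes)
    cls_idx = np.rint(np.minimum(counts[keep], n - counts[keep])).astype(int)
    cls_idx -= _k_min(n, cfg.maf_min)
    S_cls = similarity(x_classes[:, None], x_classes[None, :], cfg.sharpness_p)
    A_cls = S_cls @ e
    a_trunc = float(e.sum())
    onehot = np.zeros((n_cls, m))
    onehot[cls_idx, np.arange(m)] = 1.0
    prefix = np.concatenate(
        [np.zeros((n_cls, 1)), np.cumsum(onehot, axis=1)], axis=1
    )
    lo = np.searchsorted(pos, pos - half)
    hi = np.searchsorted(pos, pos + half + 1)
    win_counts = prefix[:, hi] - prefix[:, lo]  # classes x cores
    sim_sum = np.einsum("cm,cm->m", S_cls[cls_idx].T, win_counts) - 1.0  # drop core
    m_win = win_counts.sum(axis=0) - 1.0
    beta_raw = sim_sum / A_cls[cls_idx] - m_win / a_trunc
    empty = m_win <= 0

    eff = _effective_window_lengths(pos, half, masks, contig)
    if isinstance(theta, (int, float)):
        th = np.full(m, float(theta))
    else:
        th = np.array(
            [np.nan if (v := theta.lookup(contig, p)) is None else v for p in pos]
        )
    bad_theta = ~np.isfinite(th) | (th <= 0)
    bad_eff = eff <= 0

    df["beta_raw"] = np.where(empty, np.nan, beta_raw)
    ok = ~(empty | bad_theta | bad_eff)
    df.loc[ok, "beta_std"] = beta_raw[ok] / (th[ok] * eff[ok])
    df["masked"] = ~ok
    df.loc[empty, "reason"] = "empty-window"
    df.loc[~empty & bad_theta, "reason"] = "no-theta"
    df.loc[~empty & ~bad_theta & bad_eff, "reason"] = "zero-eff-window"
    return mask_near_indels(df, masks, cfg.indel_radius)


def _effective_window_lengths(pos, half, masks, contig) -> np.ndarray:
    """Vectorised mask-corrected window lengths around each core SNP."""
    from . import intervals as ivmod

    combined = []
    for group in (getattr(masks, "gaps", {}), getattr(masks, "repeats", {})):
        arr = group.get(contig)
        if arr is not None and len(arr):
            combined.extend(map(tuple, np.asarray(arr)))
    full = 2 * half * np.ones(len(pos))
    if not combined:
        return full
    merged = ivmod.merge(combined)
    starts, ends = merged[:, 0], merged[:, 1]
    cum = np.concatenate([[0], np.cumsum(ends - starts)])

    def coverage(x):
        # total masked bp below coordinate x
        i = np.searchsorted(starts, x, side="right")
        partial = np.clip(x - starts[np.maximum(i - 1, 0)], 0, (ends - starts)[np.maximum(i - 1, 0)])
        return cum[np.maximum(i - 1, 0)] + np.where(i > 0, partial, 0)

    return full - (coverage(pos + half) - coverage(pos - half))


def mask_near_indels(results: pd.DataFrame, masks, radius: int) -> pd.DataFrame:
    """Flag SNPs within ``radius`` bp of an indel (reason "indel").

    Already-masked rows keep their original reason. Enlarging the radius can
    only mask more SNPs, never fewer.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    out = results.copy()
    indels = getattr(masks, "indels", {})
    for contig, grp in out.groupby("contig", sort=False):
        arr = indels.get(contig)
        if arr is None or len(arr) == 0:
            continue
        arr = np.asarray(arr)
        p = grp["pos"].to_numpy()
        near = np.zeros(len(p), dtype=bool)
        for s, e in arr:
            near |= (p >= s - radius) & (p <= (e - 1) + radius)
        idx = grp.index[near & ~grp["masked"].to_numpy()]
        out.loc[idx, "masked"] = True
        out.loc[idx, "reason"] = "indel"
    return out


@dataclass
class GeneBetaSummary:
    gene_id: str
    beta_std_max: float  # NaN when no usable SNP
    n_snps_used: int
    percentile_rank: Optional[float] = None
    outlier: Optional[bool] = None


def gene_beta_max(gene, results: pd.DataFrame) -> GeneBetaSummary:
    """Max beta_std over unmasked SNPs inside the gene span (half-open)."""
    gs, ge = gene.gene_span
    sel = results[
        (results["contig"] == gene.contig)
        & (results["pos"] >= gs)
        & (results["pos"] < ge)
        & (~results["masked"])
    ]
    if len(sel) == 0:
        return GeneBetaSummary(gene.gene_id, float("nan"), 0)
    return GeneBetaSummary(
        gene.gene_id, float(sel["beta_std"].max()), int(len(sel))
    )


def outlier_call(
    candidates: list[GeneBetaSummary],
    controls: list[GeneBetaSummary],
    q: float = 95.0,
) -> list[GeneBetaSummary]:
    """Annotate candidates against the control-gene empirical distribution.

    The threshold is the nearest-rank q-th percentile of the control
    beta_std_max values; a candidate equal to the threshold is an outlier
    (>=). percentile_rank is 100 times the fraction of controls strictly
    below the candidate value.
    """
    ctrl = np.array(
        [c.beta_std_max for c in controls if np.isfinite(c.beta_std_max)]
    )
    if len(ctrl) < 20:
        raise ValueError(
            f"need >= 20 control genes with usable maxima, got {len(ctrl)}"
        )
    ctrl.sort()
    rank = int(np.ceil(q / 100.0 * len(ctrl)))
    threshold = float(ctrl[rank - 1])
    out = []
    for c in candidates:
        if not np.isfinite(c.beta_std_max):
            out.append(
                GeneBetaSummary(c.gene_id, c.beta_std_max, c.n_snps_used, None, None)
            )
            continue
        pr = 100.0 * float(np.mean(ctrl < c.beta_std_max))
        out.append(
            GeneBetaSummary(
                c.gene_id,
                c.beta_std_max,
                c.n_snps_used,
                percentile_rank=pr,
                outlier=bool(c.beta_std_max >= threshold),
            )
        )
    return out


def control_threshold(controls: list[GeneBetaSummary], q: float = 95.0) -> float:
    """Nearest-rank q-th percentile of control beta_std_max values."""
    ctrl = np.sort(
        np.array([c.beta_std_max for c in controls if np.isfinite(c.beta_std_max)])
    )
    rank = int(np.ceil(q / 100.0 * len(ctrl)))
    return float(ctrl[rank - 1])
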