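"""Core diversity estimators and the sliding-window engine.

The substrate of every statistic is a :class:`HaplotypeMatrix`: a phased
binary haplotype-by-site matrix with genomic positions. Diversity is
reported per base pair using *effective* window lengths, i.e. window size
minus the union of gap and repeat masks inside the window, so that masked
sequence does not dilute per-bp estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd

from . import intervals as iv

__all__ = [
    "HaplotypeMatrix",
    "WindowSpec",
    "DiversityStats",
    "DiversityTrack",
    "harmonic",
    "harmonic2",
    "seg_sites",
    "mean_pairwise_diff",
    "nucleotide_diversity",
    "watterson_theta",
    "tajimas_d",
    "effective_length",
    "sliding_windows",
    "theta_map",
    "ThetaMap",
]


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes.

    matrix
        uint8 array of shape ``(n_hap, n_sites)``; 1 marks the alternate
        allele.
    positions
        0-based site coordinates, strictly increasing, one per column.
    """

    matrix: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.ascontiguousarray(self.matrix, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.matrix.shape[1] != len(self.positions):
            raise ValueError("one position per matrix column required")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_hap(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def alt_counts(self) -> np.ndarray:
        return self.matrix.sum(axis=0, dtype=np.int64)

    def slice_region(self, start: int, end: int) -> "HaplotypeMatrix":
        """Columns with position in [start, end)."""
        lo, hi = np.searchsorted(self.positions, [start, end])
        return HaplotypeMatrix(self.matrix[:, lo:hi], self.positions[lo:hi])


@lru_cache(maxsize=None)
def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i, the Watterson denominator for n haplotypes."""
    return float(np.sum(1.0 / np.arange(1, n)))


@lru_cache(maxsize=None)
def harmonic2(n: int) -> float:
    """b_n = sum_{i=1}^{n-1} 1/i^2."""
    return float(np.sum(1.0 / np.arange(1, n, dtype=float) ** 2))


def seg_sites(H: HaplotypeMatrix) -> int:
    """Number of columns with both alleles present."""
    if H.n_hap == 0:
        raise ValueError("zero haplotypes")
    c = H.alt_counts()
    return int(np.count_nonzero((c > 0) & (c < H.n_hap)))


def mean_pairwise_diff(H: HaplotypeMatrix) -> float:
    """Mean number of differences over all C(n,2) haplotype pairs.

    Computed from per-site allele counts: a site with c alternate copies
    contributes c(n-c) mismatching pairs.
    """
    n = H.n_hap
    if n < 2:
        raise ValueError("need at least two haplotypes")
    c = H.alt_counts().astype(np.float64)
    return float(np.sum(c * (n - c)) / (n * (n - 1) / 2.0))


def nucleotide_diversity(H: HaplotypeMatrix, effective_length: float) -> float:
    """Per-site nucleotide diversity pi (mean pairwise difference / length)."""
    if effective_length <= 0:
        raise ValueError("effective_length must be positive")
    return mean_pairwise_diff(H) / float(effective_length)


def watterson_theta(S: int, n: int, effective_length: float) -> float:
    """Watterson's estimator per site: S / (a_n * L_effective)."""
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if effective_length <= 0:
        raise ValueError("effective_length must be positive")
    return S / (harmonic(n) * float(effective_length))


def tajimas_d(H: HaplotypeMatrix) -> float:
    """Tajima's D.

    Standardised difference between the pairwise-diversity and
    segregating-sites estimators of theta. Returns NaN when S = 0 (the
    statistic is undefined there; sliding windows routinely hit such
    windows, so this is a flagged value rather than an error).
    """
    n = H.n_hap
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4 haplotypes")
    S = seg_sites(H)
    if S == 0:
        return float("nan")
    a1 = harmonic(n)
    a2 = harmonic2(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    pi_total = mean_pairwise_diff(H)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_total - S / a1) / np.sqrt(var))


def effective_length(window, masks, contig: str) -> int:
    """Window length minus the union of gaps and repeats inside it.

    ``masks`` is a MaskSet (or anything with ``gaps``/``repeats`` dicts of
    per-contig interval arrays).
    """
    start, end = int(window[0]), int(window[1])
    if end < start:
        raise ValueError("malformed window")
    combined = []
    for group in (getattr(masks, "gaps", {}), getattr(masks, "repeats", {})):
        arr = group.get(contig)
        if arr is not None and len(arr):
            combined.extend(map(tuple, np.asarray(arr)))
    return (end - start) - iv.covered_length(combined, start, end)


@dataclass
class WindowSpec:
    start: int
    end: int
    effective_length: int


@dataclass
class DiversityStats:
    S: int
    pi_site: float
    theta_w_site: float
    tajima_d: float  # NaN when undefined (S = 0 or zero effective length)


@dataclass
class DiversityTrack:
    contig: str
    windows: list[WindowSpec] = field(default_factory=list)
    stats: list[DiversityStats] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": self.contig,
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
                "eff_len": [w.effective_length for w in self.windows],
                "S": [s.S for s in self.stats],
                "pi": [s.pi_site for s in self.stats],
                "thetaW": [s.theta_w_site for s in self.stats],
                "tajimaD": [s.tajima_d for s in self.stats],
            }
        )


def _window_starts(start: int, end: int, size: int, step: int) -> list[tuple[int, int]]:
    # Full windows anchored at the region start; a final truncated window is
    # emitted when at least a quarter of a window size remains uncovered.
    if step <= 0 or size <= 0 or step > size:
        raise ValueError("require 0 < step <= size")
    if end - start <= size:
        return [(start, end)]
    wins = []
    s = start
    while s + size <= end:
        wins.append((s, s + size))
        s += step
    last_covered = wins[-1][1]
    tail = end - last_covered
    if tail >= 0.25 * size:
        wins.append((wins[-1][0] + step, end))
    return wins


def sliding_windows(
    H: HaplotypeMatrix,
    region,
    masks,
    contig: str,
    size: int,
    step: int,
) -> DiversityTrack:
    """Per-window S, pi, Watterson's theta and Tajima's D over a region.

    Each window uses only the SNPs that fall inside it and its own
    mask-corrected effective length. A region shorter than ``size`` yields a
    single truncated window.
    """
    if hasattr(H, "haplotypes"):  # accept a VariantTable
        H = H.haplotypes()
    start, end = int(region[0]), int(region[1])
    track = DiversityTrack(contig=contig)
    for ws, we in _window_starts(start, end, size, step):
        sub = H.slice_region(ws, we)
        eff = effective_length((ws, we), masks, contig)
        S = seg_sites(sub) if sub.n_sites else 0
        if eff > 0 and S > 0:
            pi = nucleotide_diversity(sub, eff)
            tw = watterson_theta(S, H.n_hap, eff)
            d = tajimas_d(sub)
        else:
            pi, tw, d = 0.0, 0.0, float("nan")
        track.windows.append(WindowSpec(ws, we, eff))
        track.stats.append(DiversityStats(S, pi, tw, d))
    return track


@dataclass
class ThetaMap:
    """Per-tile per-bp Watterson theta lookup over fixed, non-overlapping tiles.

    Tiles with zero effective length are flagged missing; lookups outside the
    tiled extent return None, never 0.
    """

    tile: int
    tiles: dict  # (contig, tile_index) -> (theta_per_bp | nan, eff_len, S)

    def lookup(self, contig: str, pos: int) -> Optional[float]:
        key = (contig, int(pos) // self.tile)
        rec = self.tiles.get(key)
        if rec is None:
            return None
        theta, eff, _ = rec
        if eff <= 0 or not np.isfinite(theta):
            return None
        return theta

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"contig": c, "tile": t, "start": t * self.tile,
             "end": (t + 1) * self.tile, "theta_bp": th, "eff_len": eff, "S": S}
            for (c, t), (th, eff, S) in sorted(self.tiles.items())
        ]
        return pd.DataFrame(rows)


def theta_map(variants, masks, tile: int = 10_000) -> ThetaMap:
    """Watterson's theta per bp in fixed tiles (default 10 kb), mask-corrected.

    ``variants`` is a VariantTable or a dict of them keyed by contig.
    Tile origin is 0 on every contig; the tiled extent runs to the last tile
    containing a SNP.
    """
    if not isinstance(variants, dict):
        variants = {variants.contig: variants}
    tiles = {}
    for contig, vt in variants.items():
        H = vt.haplotypes()
        if H.n_sites == 0:
            continue
        n = H.n_hap
        last = int(H.positions.max()) // tile
        counts = H.alt_counts()
        segregating = (counts > 0) & (counts < n)
        pos = H.positions[segregating]
        for t in range(last + 1):
            ws, we = t * tile, (t + 1) * tile
            eff = effective_length((ws, we), masks, contig)
            lo, hi = np.searchsorted(pos, [ws, we])
            S = int(hi - lo)
            if eff <= 0:
                tiles[(contig, t)] = (float("nan"), eff, S)
            else:
                tiles[(contig, t)] = (watterson_theta(S, n, eff), eff, S)
    return ThetaMap(tile=tile, tiles=tiles)
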