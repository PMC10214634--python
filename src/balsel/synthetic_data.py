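"""Coalescent generators for haplotype data, masks, gene sets and HKA counts.

Two genealogy models are provided. The neutral model is the standard Hudson
coalescent without recombination: while k lineages remain, the waiting time
to the next coalescence is exponential with rate C(k,2) (time in units of 2N
generations). The balanced model is a two-class structured coalescent
emulating an old balanced polymorphism: haplotypes belong to allelic class A
with probability ``f_eq``; within a class of relative size f pairs coalesce
at rate 1/f, lineages exchange classes at rate ``m_switch`` each, and at
time ``t_balance`` the classes merge into a single panmictic population.
Mutations are dropped on branches as a Poisson process with rate theta/2 per
unit branch length under the infinite-sites model.

``simulate_genome`` assembles a whole synthetic study: a multi-gene phased
VCF of 62 haplotypes, gene annotations, repeat/gap/indel masks, a 20-locus
neutral HKA panel, per-gene divergence counts and a truth table flagging
which genes carry a simulated balanced polymorphism.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import io_formats as iof
from .hka import HKALocus
from .popgen_core import HaplotypeMatrix, harmonic

__all__ = [
    "SimParams",
    "SimLocus",
    "GenomeConfig",
    "SyntheticGenome",
    "simulate_neutral_locus",
    "simulate_balanced_locus",
    "simulate_hka_dataset",
    "simulate_genome",
]


@dataclass
class SimParams:
    """Parameters of a single simulated locus.

    Defaults reflect the study design being emulated: 31 diploids
    (62 haplotypes), 10-kb loci, per-bp theta of 0.002, and a balanced
    polymorphism at equilibrium frequency 0.5 that is 8 coalescent time
    units old with a class-exchange rate of 0.05.
    """

    n_hap: int = 62
    locus_len: int = 10_000
    theta_bp: float = 0.002
    model: str = "neutral"  # or "balanced"
    f_eq: float = 0.5
    m_switch: float = 0.05
    t_balance: float = 8.0
    T_div: float = 10.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_hap < 2:
            raise ValueError("n_hap must be >= 2")
        if self.theta_bp <= 0:
            raise ValueError("theta_bp must be positive")
        if not 0 < self.f_eq < 1:
            raise ValueError("f_eq must be in (0, 1)")
        if self.t_balance < 0 or self.T_div < 0:
            raise ValueError("t_balance and T_div must be non-negative")
        if self.model not in ("neutral", "balanced"):
            raise ValueError(f"unknown model {self.model!r}")

    @property
    def theta_locus(self) -> float:
        return self.theta_bp * self.locus_len


@dataclass
class SimLocus:
    haplotypes: HaplotypeMatrix
    tree_total_len: float
    class_labels: Optional[np.ndarray] = None  # balanced model only
    divergent_sites: int = 0
    balanced_site_index: Optional[int] = None


class _Tree:
    """A coalescent genealogy as parent pointers with node times."""

    def __init__(self, n: int):
        self.n = n
        total = 2 * n - 1
        self.parent = np.full(total, -1, dtype=np.int64)
        self.time = np.zeros(total, dtype=np.float64)
        self.children: list[tuple[int, int]] = []  # (left, right) per internal node

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(2 * self.n - 1)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl

    def leaf_sets(self) -> np.ndarray:
        """Boolean (2n-1, n) matrix of descendant leaves per node."""
        n = self.n
        desc = np.zeros((2 * n - 1, n), dtype=bool)
        desc[np.arange(n), np.arange(n)] = True
        for i, (a, b) in enumerate(self.children):
            desc[n + i] = desc[a] | desc[b]
        return desc


def _neutral_coalescent(n: int, rng: np.random.Generator) -> _Tree:
    tree = _Tree(n)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        tree.parent[a] = tree.parent[b] = nxt
        tree.time[nxt] = t
        tree.children.append((a, b))
        active.append(nxt)
        nxt += 1
    return tree


def _balanced_coalescent(p: SimParams, rng: np.random.Generator) -> tuple[_Tree, np.ndarray]:
    """Two-class structured coalescent merging into panmixia at t_balance."""
    n = p.n_hap
    tree = _Tree(n)
    labels = (rng.random(n) < p.f_eq).astype(np.int8)  # 1 = class A
    active = list(range(n))
    cls = list(labels)
    sizes = {1: p.f_eq, 0: 1.0 - p.f_eq}
    t = 0.0
    nxt = n
    merged = False

    def _coalesce(i: int, j: int, when: float) -> None:
        nonlocal nxt
        a, b = active[i], active[j]
        parent_cls = cls[i]  # pairs only coalesce within a class
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
            cls.pop(idx)
        tree.parent[a] = tree.parent[b] = nxt
        tree.time[nxt] = when
        tree.children.append((a, b))
        active.append(nxt)
        cls.append(parent_cls)
        nxt += 1

    while len(active) > 1:
        k = len(active)
        if merged:
            t += rng.exponential(2.0 / (k * (k - 1)))
            i, j = rng.choice(k, size=2, replace=False)
            _coalesce(i, j, t)
            continue
        idx_a = [i for i, c in enumerate(cls) if c == 1]
        idx_b = [i for i, c in enumerate(cls) if c == 0]
        ka, kb = len(idx_a), len(idx_b)
        rate_a = ka * (ka - 1) / 2.0 / sizes[1]
        rate_b = kb * (kb - 1) / 2.0 / sizes[0]
        rate_m = p.m_switch * k
        total = rate_a + rate_b + rate_m
        if total == 0:
            t = p.t_balance
            merged = True
            continue
        dt = rng.exponential(1.0 / total)
        if t + dt >= p.t_balance:
            t = p.t_balance
            merged = True
            continue
        t += dt
        u = rng.random() * total
        if u < rate_a:
            i, j = rng.choice(ka, size=2, replace=False)
            _coalesce(idx_a[i], idx_a[j], t)
        elif u < rate_a + rate_b:
            i, j = rng.choice(kb, size=2, replace=False)
            _coalesce(idx_b[i], idx_b[j], t)
        else:
            i = int(rng.integers(k))
            cls[i] = 1 - cls[i]
    return tree, labels


def _drop_mutations(
    tree: _Tree,
    theta_locus: float,
    locus_len: int,
    rng: np.random.Generator,
    position_pool: Optional[np.ndarray] = None,
    extra_columns: Optional[list[np.ndarray]] = None,
):
    """Poisson(theta/2 * L_total) mutations, uniform on branches and positions."""
    bl = tree.branch_lengths()
    total_len = float(bl.sum())
    n_mut = int(rng.poisson(theta_locus / 2.0 * total_len))
    desc = tree.leaf_sets()
    if n_mut > 0:
        branches = rng.choice(len(bl), size=n_mut, p=bl / total_len)
        cols = desc[branches]  # (n_mut, n)
    else:
        cols = np.zeros((0, tree.n), dtype=bool)
    extra = extra_columns or []
    total_sites = n_mut + len(extra)
    pool = position_pool if position_pool is not None else np.arange(locus_len)
    if total_sites > len(pool):
        raise ValueError("locus too short for the number of mutations drawn")
    positions = rng.choice(pool, size=total_sites, replace=False)
    all_cols = np.concatenate([cols.astype(np.uint8)] + [np.asarray(c, dtype=np.uint8)[None, :] for c in extra], axis=0) if extra else cols.astype(np.uint8)
    order = np.argsort(positions)
    matrix = all_cols[order].T  # n_hap x sites
    positions = positions[order]
    special = None
    if extra:
        special = int(np.where(order == total_sites - 1)[0][0])
    return HaplotypeMatrix(matrix, positions), total_len, special


def simulate_neutral_locus(params: SimParams, rng: np.random.Generator) -> SimLocus:
    """One neutral Hudson-coalescent locus under the infinite-sites model."""
    if params.model != "neutral":
        raise ValueError("params.model must be 'neutral'")
    tree = _neutral_coalescent(params.n_hap, rng)
    H, total_len, _ = _drop_mutations(tree, params.theta_locus, params.locus_len, rng)
    D = int(rng.poisson(params.theta_locus * (params.T_div + 1.0)))
    return SimLocus(haplotypes=H, tree_total_len=total_len, divergent_sites=D)


def simulate_balanced_locus(params: SimParams, rng: np.random.Generator) -> SimLocus:
    """A locus carrying an old balanced polymorphism.

    One extra "balanced site" column encodes class membership (class A = 1);
    it is omitted when the binomial class assignment happens to be
    monomorphic.
    """
    if params.model != "balanced":
        raise ValueError("params.model must be 'balanced'")
    tree, labels = _balanced_coalescent(params, rng)
    extra = []
    if 0 < labels.sum() < params.n_hap:
        extra.append(labels)
    H, total_len, special = _drop_mutations(
        tree, params.theta_locus, params.locus_len, rng, extra_columns=extra
    )
    D = int(rng.poisson(params.theta_locus * (params.T_div + 1.0)))
    return SimLocus(
        haplotypes=H,
        tree_total_len=total_len,
        class_labels=labels,
        divergent_sites=D,
        balanced_site_index=special,
    )


def simulate_unlinked_window(
    n_hap: int, theta_window: float, rng: np.random.Generator
) -> np.ndarray:
    """Folded frequencies of a neutral window of completely unlinked sites.

    In the free-recombination limit every site has its own genealogy, so the
    number of segregating sites in folded class k is Poisson with mean
    theta * e(k), e(k) = 1/k + 1/(n-k) (e(n/2) = 2/n), independently across
    classes. This is the regime in which the beta statistic is calibrated to
    zero mean under neutrality; under complete linkage the sites of a window
    share one genealogy and their frequencies cluster around any chosen
    core's frequency even without selection. Returns the folded frequency of
    every site (unfiltered), in random order.
    """
    if n_hap < 2 or theta_window <= 0:
        raise ValueError("require n_hap >= 2 and theta_window > 0")
    kmax = n_hap // 2
    ks = np.arange(1, kmax + 1)
    e = 1.0 / ks + 1.0 / (n_hap - ks)
    if n_hap % 2 == 0:
        e[-1] = 2.0 / n_hap
    counts = rng.poisson(theta_window * e)
    freqs = np.repeat(ks / n_hap, counts)
    rng.shuffle(freqs)
    return freqs


def simulate_locus(params: SimParams, rng: np.random.Generator) -> SimLocus:
    if params.model == "balanced":
        return simulate_balanced_locus(params, rng)
    return simulate_neutral_locus(params, rng)


def simulate_hka_dataset(
    theta,
    T: float,
    k,
    n: int,
    rng: np.random.Generator,
    L: int = 1000,
) -> list[HKALocus]:
    """Draw per-locus polymorphism/divergence counts from the HKA model.

    S_l ~ Poisson(k_l * theta_l * a_n) and D_l ~ Poisson(theta_l * (T + k_l)):
    the selection parameter k inflates the coalescent depth at a locus, so it
    scales polymorphism and the ancestral-polymorphism share of divergence
    (at k = 1 the divergence mean reduces to theta * (T + 1)).
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    k = np.broadcast_to(np.atleast_1d(np.asarray(k, dtype=float)), theta.shape)
    if np.any(theta <= 0) or np.any(k <= 0) or T < 0:
        raise ValueError("require theta > 0, k > 0, T >= 0")
    a = harmonic(n)
    loci = []
    for i, (th, kk) in enumerate(zip(theta, k)):
        S = int(rng.poisson(kk * th * a))
        D = int(rng.poisson(th * (T + kk)))
        loci.append(
            HKALocus(
                locus_id=f"L{i:02d}",
                S=S,
                D=D,
                n=n,
                L=L,
                is_candidate=bool(abs(kk - 1.0) > 1e-12),
            )
        )
    return loci


@dataclass
class GenomeConfig:
    """Layout of a whole synthetic study.

    Each gene sits in its own tile of ``tile_bp``; the coalescent locus spans
    the unmasked part of the full tile (so tile-level theta estimation has
    data) and the annotated gene span is an interior sub-interval. Per-tile
    theta is log-normal around ``theta_bp`` to emulate genome-wide mutation
    rate heterogeneity.
    """

    n_control: int = 200
    n_candidate: int = 5
    frac_balanced: float = 0.0  # fraction of candidate genes under balancing selection
    n_hap: int = 62
    theta_bp: float = 0.002
    theta_log_sd: float = 0.5
    tile_bp: int = 10_000
    gene_len_range: tuple[int, int] = (1000, 6000)
    linked_flank_bp: int = 1000  # sequence this close to the gene shares its genealogy
    repeat_prob: float = 0.3
    repeat_len_range: tuple[int, int] = (200, 800)
    gap_prob: float = 0.05
    gap_len_range: tuple[int, int] = (100, 400)
    indel_rate_per_tile: float = 0.2
    f_eq: float = 0.5
    m_switch: float = 0.05
    t_balance: float = 8.0
    T_div: float = 10.0
    n_hka_neutral: int = 20
    contig: str = "contig_1"
    seed: int = 0


@dataclass
class SyntheticGenome:
    variants: iof.VariantTable
    genes: list[iof.GeneModel]
    masks: iof.MaskSet
    truth: pd.DataFrame
    hka_neutral: list[HKALocus] = field(default_factory=list)
    divergence: Optional[pd.DataFrame] = None


def _random_interval(rng, lo, hi, len_range):
    ln = int(rng.integers(len_range[0], len_range[1] + 1))
    if hi - lo <= ln:
        return None
    s = int(rng.integers(lo, hi - ln))
    return (s, s + ln)


def simulate_genome(config: GenomeConfig, out_dir: Optional[str] = None) -> SyntheticGenome:
    """Generate a full synthetic study; optionally write it as files.

    Returns the in-memory objects; when ``out_dir`` is given also writes
    sim.vcf, genes.gff3, repeats.bed, gaps.bed, indels.bed, truth.tsv,
    hka_neutral.tsv and gene_divergence.tsv. Fully deterministic under
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_control + config.n_candidate
    tile = config.tile_bp
    n_balanced = int(round(config.frac_balanced * config.n_candidate))

    # candidate tiles scattered across the genome; balanced genes among candidates
    order = rng.permutation(n_genes)
    candidate_tiles = set(order[: config.n_candidate].tolist())
    balanced_tiles = set(order[:n_balanced].tolist())

    positions, refs, alts, geno_cols = [], [], [], []
    genes, truth_rows, div_rows = [], [], []
    repeats, gaps, indels = [], [], []
    bases = np.array(list("ACGT"))

    for t in range(n_genes):
        ts, te = t * tile, (t + 1) * tile
        theta_t = float(rng.lognormal(np.log(config.theta_bp), config.theta_log_sd))
        masked = []
        if rng.random() < config.repeat_prob:
            r = _random_interval(rng, ts, te, config.repeat_len_range)
            if r:
                repeats.append(r)
                masked.append(r)
        if rng.random() < config.gap_prob:
            g = _random_interval(rng, ts, te, config.gap_len_range)
            if g:
                gaps.append(g)
                masked.append(g)
        n_indel = rng.poisson(config.indel_rate_per_tile)
        for _ in range(n_indel):
            p = int(rng.integers(ts, te))
            indels.append((p, p + 1))

        is_cand = t in candidate_tiles
        is_bal = t in balanced_tiles
        glen = int(rng.integers(*config.gene_len_range))
        margin = (tile - glen) // 2
        gs = ts + margin
        ge = gs + glen
        gid = f"gene_{t:04d}"

        bad = np.zeros(tile, dtype=bool)
        for s, e in masked:
            bad[s - ts:e - ts] = True
        all_pos = np.arange(ts, te)
        ls = max(ts, gs - config.linked_flank_bp)
        le = min(te, ge + config.linked_flank_bp)
        in_gene = (all_pos >= ls) & (all_pos < le)
        pool_gene = all_pos[in_gene & ~bad]
        pool_flank = all_pos[~in_gene & ~bad]

        # the gene plus a short linked buffer rides one genealogy; distal
        # flank sequence rides an independent one. At tile scale
        # recombination decouples the selected locus from its surroundings,
        # so the 10 kb theta estimate stays anchored to the neutral rate
        # while LD within the gene (and the beta window around it) persists.
        params = SimParams(
            n_hap=config.n_hap,
            locus_len=len(pool_gene),
            theta_bp=theta_t,
            model="balanced" if is_bal else "neutral",
            f_eq=config.f_eq,
            m_switch=config.m_switch,
            t_balance=config.t_balance,
            T_div=config.T_div,
        )
        if is_bal:
            tree, labels = _balanced_coalescent(params, rng)
            extra = [labels] if 0 < labels.sum() < config.n_hap else []
        else:
            tree = _neutral_coalescent(config.n_hap, rng)
            extra = []
        Hg, _, _ = _drop_mutations(
            tree, params.theta_locus, len(pool_gene), rng,
            position_pool=pool_gene, extra_columns=extra,
        )
        flank_tree = _neutral_coalescent(config.n_hap, rng)
        Hf, _, _ = _drop_mutations(
            flank_tree, theta_t * len(pool_flank), len(pool_flank), rng,
            position_pool=pool_flank,
        )
        tile_pos = np.concatenate([Hg.positions, Hf.positions])
        tile_mat = np.concatenate([Hg.matrix, Hf.matrix], axis=1)
        order = np.argsort(tile_pos)
        tile_pos, tile_mat = tile_pos[order], tile_mat[:, order]
        positions.append(tile_pos)
        geno_cols.append(tile_mat)
        n_sites_tile = len(tile_pos)
        r = bases[rng.integers(0, 4, size=n_sites_tile)]
        shift = rng.integers(1, 4, size=n_sites_tile)
        a = bases[(np.searchsorted(bases, r) + shift) % 4]
        refs.append(r)
        alts.append(a)
        # two exons with a short intron when the gene is long enough
        if glen > 900:
            e1 = (gs, gs + (glen - 150) // 2)
            e2 = (e1[1] + 150, ge)
            exons = [e1, e2]
        else:
            exons = [(gs, ge)]
        genes.append(
            iof.GeneModel(
                gene_id=gid,
                contig=config.contig,
                strand="+",
                gene_span=(gs, ge),
                exons=exons,
                cds=exons,
            )
        )
        cds_len = sum(e - s for s, e in exons)
        D_gene = int(rng.poisson(theta_t * cds_len * (config.T_div + 1.0)))
        div_rows.append({"gene_id": gid, "D": D_gene, "L": cds_len})
        truth_rows.append(
            {
                "gene_id": gid,
                "contig": config.contig,
                "start": gs,
                "end": ge,
                "tile": t,
                "theta_bp_true": theta_t,
                "is_candidate": is_cand,
                "balanced": is_bal,
            }
        )

    pos = np.concatenate(positions)
    geno = np.concatenate(geno_cols, axis=1)
    sample_ids = []
    for i in range(config.n_hap // 2):
        sample_ids.extend([f"vole_{i + 1:02d}_1", f"vole_{i + 1:02d}_2"])
    vt = iof.VariantTable(
        contig=config.contig,
        positions=pos + 1,  # to VCF 1-based
        ref=np.concatenate(refs).astype(object),
        alt=np.concatenate(alts).astype(object),
        genotypes=geno,
        sample_ids=sample_ids,
    )
    masks = iof.MaskSet(
        repeats={config.contig: np.asarray(repeats, dtype=np.int64).reshape(-1, 2)},
        gaps={config.contig: np.asarray(gaps, dtype=np.int64).reshape(-1, 2)},
        indels={config.contig: np.asarray(indels, dtype=np.int64).reshape(-1, 2)},
    )
    truth = pd.DataFrame(truth_rows)
    divergence = pd.DataFrame(div_rows)
    theta_hka = rng.uniform(5.0, 50.0, size=config.n_hka_neutral)
    hka_neutral = simulate_hka_dataset(
        theta_hka, T=config.T_div, k=1.0, n=config.n_hap, rng=rng
    )

    genome = SyntheticGenome(
        variants=vt,
        genes=genes,
        masks=masks,
        truth=truth,
        hka_neutral=hka_neutral,
        divergence=divergence,
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        iof.write_vcf(vt, os.path.join(out_dir, "sim.vcf"), contig_length=n_genes * tile)
        iof.write_gff(genes, os.path.join(out_dir, "genes.gff3"))
        iof.write_bed(masks.repeats, os.path.join(out_dir, "repeats.bed"))
        iof.write_bed(masks.gaps, os.path.join(out_dir, "gaps.bed"))
        iof.write_bed(masks.indels, os.path.join(out_dir, "indels.bed"))
        truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
        divergence.to_csv(
            os.path.join(out_dir, "gene_divergence.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            [
                {
                    "locus_id": l.locus_id,
                    "S": l.S,
                    "D": l.D,
                    "n": l.n,
                    "L": l.L,
                    "is_candidate": l.is_candidate,
                }
                for l in hka_neutral
            ]
        ).to_csv(os.path.join(out_dir, "hka_neutral.tsv"), sep="\t", index=False)
    return genome
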