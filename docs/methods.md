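# Methods

This note documents the statistical models implemented in `balsel`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## The β statistic

A SNP maintained by long-term balancing selection drags linked neutral
variants toward its equilibrium frequency, producing a local excess of SNPs
whose folded frequencies match the selected site's. For a core SNP at folded
frequency `x_core` with neighbours at `x_i` inside a window of
`window_bp` = 2 kb centred on it, we compare two estimators of the window's
mutation supply:

    θ̂_β = Σ_i s(x_i, x_core) / A(x_core)        θ̂_W = m / a'

with the similarity kernel `s(x, y) = (1 − |x − y|/0.5)^p` (sharpness
`p = 2`), `m` the neighbour count, and normalisers summed over the folded
frequency classes `k/n` that survive the minor-allele-frequency floor
(`maf_min = 0.15`):

    A(x_core) = Σ_{k ≥ k_min} s(k/n, x_core) e(k)       a' = Σ_{k ≥ k_min} e(k)

where `e(k) = 1/k + 1/(n−k)` for `k < n/2` and `e(n/2) = 2/n` is the
expected folded site-frequency spectrum under neutrality. Then
`β = θ̂_β − θ̂_W`.

Design choices, and why:

- **MAF truncation of the normalisers.** Filtering at MAF ≥ 0.15 removes
  low-frequency classes from the data; if `A` and `a'` kept those classes
  the filter itself would bias β. Truncating both sums restores E[β] = 0
  under neutrality after filtering.
- **The core SNP is excluded from both sums.** Its similarity is 1 and its
  count is 1 *by construction*, not by chance; including it adds
  `1/A − 1/a' > 0` to every β and shifts the neutral mean visibly upward.
- **Calibration regime.** E[β] = 0 assumes neighbours sample the neutral
  folded SFS independently of the core — the loose-linkage regime in which
  the statistic is normally applied. Under *complete* linkage (one genealogy
  for the whole window, as in a single simulated non-recombining locus)
  conditioning on the core tilts the window's conditional SFS toward the
  core's frequency and β is positive (≈ +2.4 at θ_window = 10, n = 62) even
  without selection. The generator therefore provides
  `simulate_unlinked_window` — exact independent-Poisson counts per folded
  class, the free-recombination limit — and the neutral-calibration
  benchmark uses it. This is worth remembering when interpreting β on data
  with very little recombination.
- **Standardisation.** `β_std = β / (θ̂_tile · L_eff)`: β is divided by the
  expected window mutation supply, the per-bp Watterson estimate of the
  surrounding fixed 10 kb tile times the mask-corrected window length. This
  is the simplest reading of "standardised by θ" that makes values
  comparable across mutation-rate heterogeneity; it is *not* a
  variance-standardisation, and no claim of numerical equivalence to any
  external β implementation is made.
- **Windows are SNP-centred** (±1 kb around each retained SNP), matching
  per-SNP β output; fixed genomic tiles were the alternative reading.
- **Outlier call.** Gene score = max β_std over unmasked SNPs in the gene
  span; threshold = nearest-rank 95th percentile of the control genes'
  maxima; a candidate equal to the threshold is an outlier. Nearest-rank
  avoids interpolation ambiguity. Note the exchangeable-null exceedance
  probability of the ≥-nearest-rank rule is `(N − ⌈0.95N⌉ + 1)/(N + 1)`
  (≈ 0.055 at N = 200 controls), slightly above 0.05 — a property of the
  rule, not an implementation artifact.
- SNPs within `indel_radius` = 1 kb of an indel are masked before gene
  maxima are taken; masking is monotone in the radius.

## The maximum-likelihood HKA test

Per locus l with sample size `n_l` (harmonic number `a_l`), segregating
sites and divergent sites are independent Poissons:

    S_l ~ Poisson(k_l θ_l a_l)        D_l ~ Poisson(θ_l (T + k_l))

`k_l` scales the locus's effective coalescent depth: balancing selection
(k > 1) inflates polymorphism *and* the ancestral-polymorphism share of
divergence, but not the fixed divergence time T. Neutral panel loci have
k = 1; a config switch (`k_on_divergence=False`) provides the variant where
k touches only polymorphism. Given (T, k), each `θ_l` has a closed-form
maximiser `θ̂_l = (S_l + D_l)/(k_l a_l + T + k_l)`, so fitting reduces to a
1-D bounded search over T (neutral model) or a multi-start L-BFGS-B search
over (T, log k) with k ∈ [0.02, 50] (selection model). The LRT statistic
`max(0, 2Δℓ)` is referred to χ² with one degree of freedom per free k. A
Metropolis chain maximiser over the same likelihood is available
(`method="chain"`) purely as a cross-check of the direct optimiser.

The χ² reference is asymptotic in the counts: at the benchmark's θ ∈ [5, 50]
the measured type-I error is statistically compatible with nominal
(0.047 at α = 0.05 over 3000 replicates), and converges visibly at large θ.
Divergence counting from CDS alignments removes every column containing a
gap, then compares the outgroup against one seed-chosen ingroup haplotype.

## Diversity statistics and windows

π is the mean pairwise difference over all C(n,2) haplotype pairs (per site
after dividing by the effective length); θ̂_W = S/(a_n L_eff); Tajima's D
uses the standard constants and returns NaN (flagged, not an error) when
S = 0. Effective lengths subtract the union of gap and repeat masks from
each window. Sliding windows tile a region from its start (2 kb / 500 bp by
default; 500 / 50 bp automatically for genes shorter than 4 windows); a
final truncated window is emitted only if at least a quarter of a window
remains uncovered — a deterministic rule chosen because any convention
works as long as it is fixed. The θ map uses fixed, non-overlapping 10 kb
tiles anchored at coordinate 0; tiles with zero effective length are
flagged missing and SNPs falling in them are masked "no-theta" rather than
given θ = 0.

## LD blocks and haplotype networks

D′ is computed by direct haplotype counting. Its confidence bounds come from
the multinomial likelihood of the four observed haplotype counts evaluated
on a 1001-point D′ grid at fixed margins, normalised to unit mass; the
5th/95th mass percentiles are the bounds, expanded if necessary to contain
the point estimate. Pairs are "strong LD" if `ci_low ≥ 0.70` and
`ci_high ≥ 0.98`, "strong recombination" if `ci_high < 0.90`; a run of SNPs
is a block when ≥ 95% of its informative pairs are strong LD, with blocks
accepted greedily longest-first without overlap. Thresholds are the
published defaults of the confidence-interval block method and sit in
`LDBlockConfig`.

Median-joining networks (ε = 0) start from the minimum-spanning network
(union of all minimum spanning trees, i.e. Kruskal admitting every tie),
then repeatedly insert the majority-consensus median of a feasible triplet
(two of its three pairs linked) that most reduces the minimum-spanning-tree
length, to a fixed point; peripheral inferred vectors (degree ≤ 1) are
pruned. Ties are broken lexicographically, making the construction fully
deterministic. Multi-state input is reduced to binary presence of the
non-reference allele. The two-group summary cuts the network's minimum
spanning backbone at its heaviest edge and reports the observed-frequency
totals on both sides — a descriptive statistic, not a test.

## The synthetic-data generator

`simulate_neutral_locus` is a standard Hudson coalescent without
recombination (exponential waiting times at rate C(k,2), Poisson(θ/2 × tree
length) infinite-sites mutations, uniform positions).
`simulate_balanced_locus` is the two-class structured coalescent described
in the README; the balanced site itself is emitted as an extra column
encoding class membership. Defaults mirror the emulated study design:
n = 62 haplotypes (31 diploids), f_eq = 0.5, t_balance = 8, m_switch = 0.05,
θ = 0.002/bp with log-normal (σ = 0.5) tile-to-tile heterogeneity — a
realistic diversity level for an abundant wild rodent — and outgroup
divergence T = 10 (in 2N-generation units), giving divergence-to-diversity
ratios of the order seen between a vole and the house mouse.

`simulate_genome` lays one gene per 10 kb tile (gene lengths 1–6 kb,
centred), with occasional repeats, gaps and indel points; SNP positions
avoid masked sequence, so mask-corrected θ estimation is exact rather than
approximate. Within a tile, the gene plus a 1 kb linked buffer rides one
genealogy and the distal flanks ride an independent one: over 10 kb real
recombination decouples a selected locus from most of its θ-estimation
window, and without this decoupling a balanced gene inflates its own tile θ̂
and cancels its β_std signal. HKA divergence counts are drawn directly from
the Poisson model above rather than from a simulated outgroup branch,
giving a clean parameter-recovery loop for the test.

What the generator does **not** emulate: recombination *within* a linked
segment (LD inside a gene is complete, so simulated LD blocks are maximal),
demographic history (no growth, bottlenecks or structure beyond the
balanced classes), sequencing or phasing error, multiallelic sites, and
selective sweeps. Passing tests therefore demonstrate the statistics'
behaviour under their own model assumptions — unbiasedness, calibration,
power against the intended signal — not robustness to demography or data
artifacts.

Measured behaviour worth knowing: with m_switch = 0.05 roughly a quarter of
balanced draws lose their deep split (a class exchange during the long
two-lineage phase lets the sampled classes coalesce early), so end-to-end
detection power of the full pipeline at the default conditions is ~0.7,
while the rank-AUC of β_std.max against neutral genes is ≈ 0.94 — the weak
tail of collapsed draws hurts a 95th-percentile call more than it hurts a
rank statistic.

## Benchmarks and problem sizes

`balsel.evaluation` fixes the validation designs: 2000 unlinked neutral
windows for β calibration; 500 balanced + 500 neutral loci for the AUC; 500
replicate 20+1-locus panels (θ ∈ [5, 50], T = 2, n = 62) for ML-HKA type-I
error and k-recovery (k = 2.72); 5000 neutral replicates for estimator
bias; 300-gene θ-heterogeneous genomes for the standardisation-slope check;
and 200 all-neutral 205-gene genomes for the end-to-end null outlier rate.
These sizes keep every Monte-Carlo standard error small relative to the
assertion tolerances while the whole battery runs in a couple of minutes.
All experiments are deterministic given a seed.
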