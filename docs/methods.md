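# Methods

This note documents the statistical procedures, the simulator, the default
parameters, and the numerical choices behind `rohscan`.

## Genotype model and I/O

Genotypes are diploid autosomal SNP calls stored as allele2 dosages
{0, 1, 2} with −1 for missing. Allele2 is the second allele column of a
BIM/MAP-style map; no frequency-based re-polarisation is ever applied, so
BED/BIM/FAM round trips are bit-exact. PED files carry no allele columns, so
the reader derives each SNP's coding from first appearance in the file;
round trips through PED preserve genotype content exactly but may swap the
(arbitrary) allele1/allele2 labels per SNP. Coordinates are 1-based bp;
every length downstream is `(end_bp − start_bp)/1000` kb. Chromosome labels
are strings; the autosome set (default `1`–`28`, the chicken chip
convention) is a configuration value.

## SNP quality control

Three per-SNP statistics are computed over non-missing calls: minor allele
frequency, the exact Hardy–Weinberg p-value, and call rate. A SNP is removed
when **any** statistic is at or below its threshold (defaults 0.05, 10⁻⁴,
0.95). The inclusive boundary follows the screening protocol's wording;
PLINK's `--maf`/`--geno` use different boundary conventions, and this
divergence is deliberate and documented here.

The HWE test is the standard two-sided exact conditional test: given the
observed allele counts, the probability of every compatible heterozygote
count is evaluated by the well-known recurrence from the modal count, and
the p-value sums all configurations whose probability does not exceed the
observed one (plain formulation, not mid-p; a 10⁻¹² relative guard admits
mathematically tied configurations despite rounding). Monomorphic SNPs get
p = 1 and are instead removed by the MAF rule.

HWE scope: the default tests all samples pooled — what a naive run on a
merged multi-population file does — and a `per_population` mode takes the
minimum p across populations, because pooled HWE on many differentiated
populations is dominated by the Wahlund effect. Which scope the original
screening protocol used is not stated; both are provided.

## ROH detection and F_ROH

Per sample and chromosome, every window of 50 consecutive SNPs is labelled
homozygous iff it contains ≤ 1 heterozygous and ≤ 5 missing calls; each
SNP's hit rate is the fraction of covering windows that are homozygous, and
the SNP is flagged at hit rate ≥ 0.05. Maximal runs of flagged SNPs are
split where adjacent SNPs are > 1000 kb apart and kept iff they contain
≥ 100 SNPs, span ≥ 1000 kb, and average ≤ 50 kb per SNP. Segment endpoints
are the first/last flagged SNP. The window geometry (50 SNPs, ≤ 1 het) and
the segment minima (100 SNPs, 1000 kb, 1 SNP/50 kb) are the screening
protocol's settings; the remaining knobs (5 missing per window, hit
threshold 0.05, 1000-kb gap) take PLINK 1.9's defaults, since that is the
tool the protocol ran. The density rule is enforced as average spacing
(PLINK's `--homozyg-density` semantics). Chromosomes shorter than one
window fall back to flagging plain homozygous calls.

`F_ROH` is the summed segment length over `L`, the SNP-covered autosomal
length (per chromosome, last minus first marker on the working map —
"covered by SNPs", not assembly length).

Population summaries report mean ± SE (sample sd with n−1 over √n; SE = 0
for n = 1), minimum and maximum of the per-individual ROH count and ROH
length, and mean ± SE of F_ROH. "ROH length" of an individual is the *mean*
of its segment lengths by default (matching the kb magnitudes such tables
print); a `total` metric is also computed. Individuals without segments
contribute 0.

The purity screen classifies a population as `purebred-like` when its mean
per-individual ROH count exceeds 20, `crossbred-like` below 6, and
`indeterminate` between — deliberately a screen with an inconclusive band,
not a classifier; real purebred populations do fall in the gap.

## Linkage disequilibrium

For a SNP pair, haplotype frequencies are maximum-likelihood estimates
under random gamete pairing via the classic two-locus EM: only the double
heterozygote is phase-ambiguous and is split between coupling and repulsion
in proportion to their current expected products. Initialisation is at
linkage equilibrium, convergence at max |Δf| < 10⁻¹⁰ or 1000 iterations;
individuals missing either call are dropped (complete case); a locus
monomorphic among retained individuals makes r² undefined (the denominator
of the r² formula vanishes) and raises a typed error.

Per-population mean LD uses **all adjacent same-chromosome pairs** by
default (a `window_kb` scheme is available), reporting mean ± SE over pairs
and the count of skipped (undefined) pairs. PLINK's default r² report drops
pairs with r² < 0.2; that convention is deliberately *not* replicated
because it inflates means — absolute mean-LD values are therefore
comparable between populations within this package but not with such
filtered reports.

## Population structure

**IBS distances.** Per SNP, two samples share
`2 − |d_i − d_j| − [both het]` alleles (identical homozygotes 2, hom/het 1,
het/het 1, opposite homozygotes 0); distance is one minus the shared
fraction over jointly called SNPs. This matches PLINK's `1 − DST`
convention with het/het scored as one shared pair. Sex chromosomes should
be excluded beforehand (`restrict_chroms`), as the pipeline driver does.

**Classical MDS.** Torgerson double-centering `B = −½ J D² J`, exact
eigendecomposition, coordinates = top-k eigenvectors × √eigenvalue. Axis
signs are mathematically arbitrary and fixed by making each axis'
largest-magnitude coordinate positive; if fewer than k eigenvalues are
positive the embedding truncates with a warning.

**F_ST.** The Hudson-type estimator per SNP —
`(p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)` over
`p₁(1−p₂) + p₂(1−p₁)`, n in allele counts — aggregated as a ratio of sums
over SNPs (the eigensoft convention, robust to rare SNPs). SNPs monomorphic
across a pair are skipped. Estimates can be slightly negative for
undifferentiated pairs; `clamped()` floors them at 0 for tree input. The
genotype-based two-population Weir–Cockerham θ is available as an option.

**Neighbor joining.** Standard Saitou–Nei with the Q criterion. Ties are
broken by the lexicographically smallest label pair and taxa are processed
in sorted label order, so output is deterministic and invariant to input
order (PHYLIP's input-order behaviour is not emulated). Branch lengths may
be negative, as in PHYLIP. Leaves with Newick metacharacters are quoted.

## The simulator

The generator emulates a 60K-chip-like panel at reduced scale and the
population structure the screen assumes.

* **Genome**: 5 chromosomes × 50 Mb, markers every 25 kb (10,000 SNPs),
  linear genetic map at 1 cM/Mb. This keeps the marker density of a real
  chip (~1 SNP/20 kb) while shrinking the genome ~4× so the full pipeline
  runs in seconds; consequently *absolute per-individual ROH counts scale
  down ~4×* relative to a full autosome set at equal autozygosity.
* **Base allele frequencies**: uniform on [0.05, 0.95] per SNP, shared by
  all breeds, so divergence between breeds is pure drift.
* **Breeds**: `n_founders` unrelated founders (Bernoulli haplotypes), then
  `n_generations` of closed random mating at `census_size` with two
  distinct parents per offspring (no selfing). Default 4 founders,
  20 generations, census 20 — a deliberately strong bottleneck giving
  pedigree F ≈ 0.4–0.45 and pairwise F_ST between lines of ~0.4–0.5.
  A lone founder (`n_founders=1`) is taken as fully inbred so the line is
  degenerate (autozygous everywhere) immediately.
* **Meiosis**: Poisson crossover count per chromosome
  (λ = Mb × cM/Mb ÷ 100) at uniform positions, no interference, no
  mutation, no selection.
* **Truth**: every founder haplotype carries a unique ancestry label that
  recombines with the alleles, so realised autozygosity is exact; pedigree
  F comes from the exact kinship recursion (tabular method). F1 offspring
  of distinct pools have pedigree F = 0; a self-crossed breed pool uses its
  kinship matrix.
* **Crosses**: one recombined gamete from a random parent in each pool;
  pools compose, so `"C x (SL x A)"` gives three-way F1s with breed
  fractions 0.5/0.25/0.25. Unparenthesised chains associate to the right.

What the simulator does **not** model: real chicken karyotype (macro/micro
chromosomes with strongly varying recombination), marker ascertainment,
genotyping error, mutation, selection, or the actual breed histories.
Passing tests therefore demonstrate that the statistics recover the known
truth of this idealised process — not that any particular real population
is pure or crossbred.

## Problem sizes and observed behaviour

The test suite and the acceptance script run everything at the scales above
(10k SNPs, ≤ ~130 samples), chosen so each stage completes in seconds. On
the default panel (seed 1) the screen separates the groups perfectly: every
F1 cross yields zero qualifying segments, every closed line ~10–12 long
segments with F_ROH 0.38–0.49. Note the absolute purebred counts sit below
the full-genome ">20" purebred threshold purely through the 4×-smaller
genome (the per-Mb segment density, ~0.05/Mb, matches or exceeds deeply
inbred full-genome profiles); the "<6" crossbred threshold is scale-robust
because the F1 expectation is ~0.

## Numerical choices

* HWE: recurrence from the modal heterozygote count; tie guard 10⁻¹²
  relative.
* EM: equilibrium start makes the first double-het split 50/50; tolerance
  10⁻¹⁰ on frequencies.
* r² is clipped to [0, 1] only for float overshoot ≤ 10⁻¹²; anything larger
  is an error.
* ROH length comparisons carry a 10⁻⁹-kb guard so "≥ 1000 kb" and
  "≤ 50 kb/SNP" behave inclusively under floating point.
* All randomness flows from a single `numpy` `default_rng(seed)` per
  scenario; identical seeds give byte-identical output files.
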