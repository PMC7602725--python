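"""Forward-in-time simulation of small closed breeds and F1 crosses.

The generator produces SNP-chip-like genotype panels with the population
structure the ROH screen assumes: several divergent purebred lines with
tunable autozygosity (small census, tens of closed generations) and two- or
three-way F1 crosses between them, plus a per-sample truth table (pedigree
inbreeding, realised autozygosity, breed-of-origin fractions) for
validation.

Model
-----
* A genome of ``n_chrom`` equally sized chromosomes carries markers on a
  regular ``snp_spacing_bp`` grid; the genetic map is linear at
  ``recomb_rate_cm_per_mb`` cM/Mb.
* Base allele frequencies are drawn once per SNP from a uniform law on
  ``freq_range`` and shared by all breeds, so between-breed divergence
  arises purely from drift.
* Each breed starts from ``n_founders`` unrelated founders whose phased
  haplotypes are Bernoulli draws from the base frequencies, then undergoes
  ``n_generations`` of closed random mating at ``census_size`` (two distinct
  parents per offspring; no selfing, selection or mutation).
* Meiosis places a Poisson number of crossovers per chromosome
  (lambda = length_Mb x cM/Mb / 100) at uniform positions, without
  interference.
* Every founder haplotype carries a unique ancestry label that recombines
  alongside the alleles, so realised identity-by-descent is known exactly;
  pedigree inbreeding is tracked through the exact kinship recursion.

Crosses take one recombined gamete from a random parent in each pool and
compose: crossing a pool with a previous cross's offspring pool yields
three-way F1s.  Cross expressions use ``x`` (or the multiplication sign)
with parentheses, e.g. ``"C x (BL x SL)"``; an unparenthesised chain
associates to the right.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, Sample, SNPRecord
from .plink import write_genotypes


@dataclass(frozen=True)
class BreedSpec:
    """One closed purebred line: founders, closed generations, census size."""

    name: str
    n_founders: int = 4
    n_generations: int = 20
    census_size: int = 20

    def __post_init__(self):
        if self.n_founders < 1 or self.census_size < 2 or self.n_generations < 0:
            raise ValueError(f"invalid breed spec for {self.name}")


@dataclass(frozen=True)
class CrossSpec:
    """An F1 cross, e.g. ``expression="BR1 x BR2"`` or ``"BR3 x (BR1 x BR2)"``."""

    name: str
    expression: str
    n_offspring: int = 14


@dataclass
class SimScenario:
    """Full description of a simulated panel; ``seed`` fixes every output."""

    breeds: list[BreedSpec]
    crosses: list[CrossSpec] = field(default_factory=list)
    n_chrom: int = 5
    chrom_length_bp: int = 50_000_000
    snp_spacing_bp: int = 25_000
    recomb_rate_cm_per_mb: float = 1.0
    freq_range: tuple[float, float] = (0.05, 0.95)
    sample_sizes: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_chrom < 1 or self.chrom_length_bp < self.snp_spacing_bp:
            raise ValueError("invalid genome geometry")
        lo, hi = self.freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("freq_range must lie strictly inside (0, 1)")
        names = [b.name for b in self.breeds] + [c.name for c in self.crosses]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names in scenario")


class Genome:
    """Marker grid and genetic map shared by all simulated populations."""

    def __init__(self, n_chrom: int, chrom_length_bp: int, spacing_bp: int,
                 recomb_rate_cm_per_mb: float):
        self.n_chrom = n_chrom
        self.chrom_length_bp = chrom_length_bp
        self.recomb_rate = recomb_rate_cm_per_mb
        pos = np.arange(spacing_bp, chrom_length_bp + 1, spacing_bp, dtype=np.int64)
        self.chrom_positions = [pos.copy() for _ in range(n_chrom)]
        self.snps_per_chrom = pos.size
        self.n_snps = pos.size * n_chrom
        # crossovers per meiosis per chromosome
        self.xover_lambda = chrom_length_bp / 1e6 * recomb_rate_cm_per_mb / 100.0

    def chrom_slice(self, c: int) -> slice:
        return slice(c * self.snps_per_chrom, (c + 1) * self.snps_per_chrom)

    def snp_records(self) -> list[SNPRecord]:
        recs = []
        for c in range(self.n_chrom):
            for j, bp in enumerate(self.chrom_positions[c]):
                recs.append(
                    SNPRecord(
                        chrom=str(c + 1),
                        snp_id=f"snp{c + 1}_{j + 1}",
                        genetic_pos=bp / 1e6 * self.recomb_rate,
                        bp_pos=int(bp),
                        allele1="A",
                        allele2="B",
                    )
                )
        return recs


@dataclass
class HaplotypePool:
    """A phased population: alleles and ancestry labels per haplotype.

    ``alleles``/``ancestry`` have shape ``(n_individuals, 2, n_snps)``;
    ancestry holds globally unique founder-haplotype ids, so a locus is
    autozygous iff the two labels agree.  ``kinship`` is the pedigree
    kinship matrix of the current generation (``None`` for cross offspring);
    ``f_pedigree`` is the pedigree inbreeding coefficient per individual and
    ``breed_fractions`` maps breed name -> per-individual ancestry fraction.
    """

    genome: Genome
    alleles: np.ndarray
    ancestry: np.ndarray
    f_pedigree: np.ndarray
    breed_fractions: dict[str, np.ndarray]
    kinship: np.ndarray | None = None

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    def f_realized(self) -> np.ndarray:
        """Realised autozygosity: genome fraction where the two ancestry
        labels coincide."""
        return (self.ancestry[:, 0, :] == self.ancestry[:, 1, :]).mean(axis=1)

    def dosages(self) -> np.ndarray:
        """Unphased allele2 dosage matrix (individuals x SNPs)."""
        return self.alleles.sum(axis=1).astype(np.int8)

    def heterozygosity(self) -> np.ndarray:
        """Observed per-individual heterozygosity."""
        return (self.alleles[:, 0, :] != self.alleles[:, 1, :]).mean(axis=1)


def _meiosis(genome: Genome, alleles: np.ndarray, ancestry: np.ndarray,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a phased parent: Poisson crossovers, uniform positions."""
    gam_a = np.empty(genome.n_snps, dtype=alleles.dtype)
    gam_t = np.empty(genome.n_snps, dtype=ancestry.dtype)
    for c in range(genome.n_chrom):
        sl = genome.chrom_slice(c)
        pos = genome.chrom_positions[c]
        n_x = rng.poisson(genome.xover_lambda)
        start = rng.integers(2)
        if n_x == 0:
            hap = np.full(pos.size, start)
        else:
            breaks = np.sort(rng.integers(1, genome.chrom_length_bp, size=n_x))
            hap = (start + np.searchsorted(breaks, pos)) % 2
        idx = np.arange(pos.size)
        gam_a[sl] = alleles[hap, sl.start + idx]
        gam_t[sl] = ancestry[hap, sl.start + idx]
    return gam_a, gam_t


def simulate_breed(
    genome: Genome,
    base_freqs: np.ndarray,
    spec: BreedSpec,
    rng: np.random.Generator,
    founder_id_start: int = 0,
) -> HaplotypePool:
    """Simulate one closed breed and return its final-generation pool.

    Founder haplotypes are per-SNP Bernoulli draws from ``base_freqs``;
    ancestry labels start at ``founder_id_start`` (pass distinct offsets per
    breed so labels stay globally unique).
    """
    nf = spec.n_founders
    alleles = (
        rng.random((nf, 2, genome.n_snps)) < base_freqs[None, None, :]
    ).astype(np.int8)
    ancestry = (
        founder_id_start + np.arange(2 * nf, dtype=np.int32).reshape(nf, 2)
    )[:, :, None] * np.ones(genome.n_snps, dtype=np.int32)
    kinship = 0.5 * np.eye(nf)
    f_ped = np.zeros(nf)
    if nf == 1:
        # a lone founder is taken as fully inbred (its two haplotypes
        # identical), so the line is degenerate: autozygous everywhere
        alleles[0, 1] = alleles[0, 0]
        ancestry[0, 1] = ancestry[0, 0]
        kinship[:] = 1.0
        f_ped[:] = 1.0

    pool = HaplotypePool(
        genome=genome,
        alleles=alleles,
        ancestry=ancestry,
        f_pedigree=f_ped,
        breed_fractions={spec.name: np.ones(nf)},
        kinship=kinship,
    )
    for _ in range(spec.n_generations):
        pool = _advance_generation(pool, spec.census_size, spec.name, rng)
    return pool


def _advance_generation(
    pool: HaplotypePool, census: int, name: str, rng: np.random.Generator
) -> HaplotypePool:
    """One generation of closed random mating (two distinct parents each)."""
    n = pool.n_individuals
    genome = pool.genome
    alleles = np.empty((census, 2, genome.n_snps), dtype=np.int8)
    ancestry = np.empty((census, 2, genome.n_snps), dtype=np.int32)
    sires = np.empty(census, dtype=int)
    dams = np.empty(census, dtype=int)
    for i in range(census):
        if n >= 2:  # two distinct parents; a lone founder must self
            pa, pb = rng.choice(n, size=2, replace=False)
        else:
            pa = pb = 0
        sires[i], dams[i] = pa, pb
        alleles[i, 0], ancestry[i, 0] = _meiosis(
            genome, pool.alleles[pa], pool.ancestry[pa], rng
        )
        alleles[i, 1], ancestry[i, 1] = _meiosis(
            genome, pool.alleles[pb], pool.ancestry[pb], rng
        )

    K = pool.kinship
    if K is None:
        K = 0.5 * np.eye(n)
    # tabular method: kinship of offspring i, j = average kinship of i's
    # parents with j's parents; self-kinship = (1 + F_i) / 2
    K_new = 0.25 * (
        K[np.ix_(sires, sires)]
        + K[np.ix_(sires, dams)]
        + K[np.ix_(dams, sires)]
        + K[np.ix_(dams, dams)]
    )
    f_ped = K[sires, dams]
    np.fill_diagonal(K_new, 0.5 * (1.0 + f_ped))
    return HaplotypePool(
        genome=genome,
        alleles=alleles,
        ancestry=ancestry,
        f_pedigree=f_ped,
        breed_fractions={name: np.ones(census)},
        kinship=K_new,
    )


def make_cross(
    pool_a: HaplotypePool,
    pool_b: HaplotypePool,
    n_offspring: int,
    rng: np.random.Generator,
) -> HaplotypePool:
    """F1 offspring taking one recombined gamete from a random parent in each
    pool.  Composable: either pool may itself be cross offspring."""
    if pool_a.n_individuals == 0 or pool_b.n_individuals == 0:
        raise ValueError("parental pools must be non-empty")
    genome = pool_a.genome
    alleles = np.empty((n_offspring, 2, genome.n_snps), dtype=np.int8)
    ancestry = np.empty((n_offspring, 2, genome.n_snps), dtype=np.int32)
    f_ped = np.zeros(n_offspring)
    same_pool = pool_a is pool_b
    fracs: dict[str, list[float]] = {}
    for i in range(n_offspring):
        pa = int(rng.integers(pool_a.n_individuals))
        pb = int(rng.integers(pool_b.n_individuals))
        if same_pool and pool_a.n_individuals > 1:
            while pb == pa:
                pb = int(rng.integers(pool_b.n_individuals))
        alleles[i, 0], ancestry[i, 0] = _meiosis(
            genome, pool_a.alleles[pa], pool_a.ancestry[pa], rng
        )
        alleles[i, 1], ancestry[i, 1] = _meiosis(
            genome, pool_b.alleles[pb], pool_b.ancestry[pb], rng
        )
        if same_pool and pool_a.kinship is not None:
            f_ped[i] = pool_a.kinship[pa, pb]
        for breed in set(pool_a.breed_fractions) | set(pool_b.breed_fractions):
            fa = pool_a.breed_fractions.get(breed)
            fb = pool_b.breed_fractions.get(breed)
            va = float(fa[pa]) if fa is not None else 0.0
            vb = float(fb[pb]) if fb is not None else 0.0
            fracs.setdefault(breed, [0.0] * n_offspring)[i] = 0.5 * (va + vb)
    return HaplotypePool(
        genome=genome,
        alleles=alleles,
        ancestry=ancestry,
        f_pedigree=f_ped,
        breed_fractions={k: np.asarray(v) for k, v in fracs.items()},
        kinship=None,
    )


# -- cross-expression parsing ----------------------------------------------

_TOKEN = re.compile(r"\s*([A-Za-z0-9_.\-]+|\(|\)|x|×)\s*")


def _tokenize(expr: str) -> list[str]:
    out, i = [], 0
    while i < len(expr):
        m = _TOKEN.match(expr, i)
        if not m:
            raise ValueError(f"cannot parse cross expression {expr!r} at {expr[i:]!r}")
        out.append(m.group(1))
        i = m.end()
    return out


def _parse_expr(tokens: list[str], pos: int = 0):
    """expr := term ('x' expr)?   (right-associative); term := NAME | '(' expr ')'"""
    def term(p):
        if tokens[p] == "(":
            node, p = expr(p + 1)
            if p >= len(tokens) or tokens[p] != ")":
                raise ValueError("unbalanced parentheses in cross expression")
            return node, p + 1
        if tokens[p] in ("x", "×", ")"):
            raise ValueError(f"unexpected token {tokens[p]!r} in cross expression")
        return tokens[p], p + 1

    def expr(p):
        left, p = term(p)
        if p < len(tokens) and tokens[p] in ("x", "×"):
            right, p = expr(p + 1)
            return (left, right), p
        return left, p

    node, p = expr(pos)
    if p != len(tokens):
        raise ValueError("trailing tokens in cross expression")
    return node


def resolve_cross(
    expression: str,
    pools: dict[str, HaplotypePool],
    n_offspring: int,
    rng: np.random.Generator,
    intermediate_offspring: int | None = None,
) -> HaplotypePool:
    """Evaluate a cross expression against named pools.

    Intermediate (parenthesised) crosses produce ``intermediate_offspring``
    individuals (default: ``n_offspring``) that serve as the parental pool of
    the enclosing cross.
    """
    tree = _parse_expr(_tokenize(expression))
    inter = intermediate_offspring or n_offspring

    def build(node, final: bool) -> HaplotypePool:
        if isinstance(node, str):
            if node not in pools:
                raise KeyError(f"cross expression references unknown breed {node!r}")
            return pools[node]
        left, right = node
        a = build(left, False)
        b = build(right, False)
        return make_cross(a, b, n_offspring if final else inter, rng)

    return build(tree, True)


# -- end-to-end panel -------------------------------------------------------

def default_scenario(seed: int = 0) -> SimScenario:
    """A panel mirroring a germplasm-collection study design: four closed
    purebred lines, two two-way F1 crosses and one three-way F1 cross on a
    five-chromosome, ~10k-SNP chip-like map."""
    breeds = [BreedSpec(name=f"BR{i + 1}") for i in range(4)]
    crosses = [
        CrossSpec(name="BR1xBR2", expression="BR1 x BR2"),
        CrossSpec(name="BR3xBR4", expression="BR3 x BR4"),
        CrossSpec(name="BR3x(BR1xBR2)", expression="BR3 x (BR1 x BR2)"),
    ]
    return SimScenario(breeds=breeds, crosses=crosses, seed=seed)


def simulate_panel(
    scenario: SimScenario,
    out_prefix=None,
    out_format: str = "ped",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate the whole panel of a scenario.

    Returns the unphased :class:`GenotypeMatrix` (all populations stacked)
    and the truth table (``sample_id``, ``population``, ``f_pedigree``,
    ``f_realized``, one ``frac_<breed>`` column per breed).  When
    ``out_prefix`` is given, also writes the PLINK file set and
    ``<out_prefix>.truth.tsv``.  Byte-identical output for a fixed scenario.
    """
    rng = np.random.default_rng(scenario.seed)
    genome = Genome(
        scenario.n_chrom,
        scenario.chrom_length_bp,
        scenario.snp_spacing_bp,
        scenario.recomb_rate_cm_per_mb,
    )
    lo, hi = scenario.freq_range
    base_freqs = rng.uniform(lo, hi, size=genome.n_snps)

    pools: dict[str, HaplotypePool] = {}
    offset = 0
    for spec in scenario.breeds:
        pools[spec.name] = simulate_breed(genome, base_freqs, spec, rng, offset)
        offset += 2 * spec.n_founders
    for cross in scenario.crosses:
        pools[cross.name] = resolve_cross(
            cross.expression, pools, cross.n_offspring, rng
        )

    sizes = dict(scenario.sample_sizes or {})
    samples: list[Sample] = []
    dosage_rows = []
    truth_rows = []
    breed_names = [b.name for b in scenario.breeds]
    for name in [b.name for b in scenario.breeds] + [c.name for c in scenario.crosses]:
        pool = pools[name]
        want = sizes.get(name, pool.n_individuals)
        if want > pool.n_individuals:
            raise ValueError(
                f"requested {want} samples from {name} but pool has "
                f"{pool.n_individuals}"
            )
        chosen = np.sort(rng.choice(pool.n_individuals, size=want, replace=False))
        dos = pool.dosages()[chosen]
        f_real = pool.f_realized()[chosen]
        for rank, idx in enumerate(chosen):
            sid = f"{name}_{rank + 1:03d}"
            samples.append(Sample(sample_id=sid, population=name, sex=1 + rank % 2))
            row = {
                "sample_id": sid,
                "population": name,
                "f_pedigree": float(pool.f_pedigree[idx]),
                "f_realized": float(f_real[rank]),
            }
            for breed in breed_names:
                frac = pool.breed_fractions.get(breed)
                row[f"frac_{breed}"] = float(frac[idx]) if frac is not None else 0.0
            truth_rows.append(row)
        dosage_rows.append(dos)

    calls = np.vstack(dosage_rows)
    g = GenotypeMatrix(samples, genome.snp_records(), calls)
    truth = pd.DataFrame(truth_rows)

    if out_prefix is not None:
        write_genotypes(g, out_prefix, format=out_format)
        truth.to_csv(f"{out_prefix}.truth.tsv", sep="\t", index=False,
                     float_format="%.8g")
    return g, truth
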