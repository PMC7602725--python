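"""Two-locus linkage disequilibrium from unphased genotypes.

Haplotype frequencies are maximum-likelihood estimates under random pairing
of gametes, obtained with the classic two-locus EM: every genotype pair
except the double heterozygote determines its two haplotypes outright; the
double heterozygote is split between the coupling (A1B1/A2B2) and repulsion
(A1B2/A2B1) phases in proportion to their current expected frequencies.

The LD statistic is the squared correlation

    r^2 = (f11*f22 - f12*f21)^2 / (fA1*fA2*fB1*fB2)

where f11..f22 are the four haplotype frequencies and fA1, fA2, fB1, fB2 the
allele frequencies at the two loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

EM_TOL = 1e-10
EM_MAX_ITER = 1000


class LDUndefinedError(ValueError):
    """Raised when r^2 is undefined (a locus monomorphic in the sample)."""


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Two-locus haplotype and allele frequencies (A1B1, A1B2, A2B1, A2B2)."""

    f11: float
    f12: float
    f21: float
    f22: float
    n_pairs: int  # complete-case individuals used
    n_iter: int  # EM iterations run (0 when no double heterozygotes)

    @property
    def fA1(self) -> float:
        return self.f11 + self.f12

    @property
    def fA2(self) -> float:
        return self.f21 + self.f22

    @property
    def fB1(self) -> float:
        return self.f11 + self.f21

    @property
    def fB2(self) -> float:
        return self.f12 + self.f22


@dataclass(frozen=True)
class LDValue:
    snp_a: str
    snp_b: str
    r2: float
    bp_distance: int


def em_haplotype_freqs(
    genos_a: np.ndarray, genos_b: np.ndarray
) -> HaplotypeFreqs:
    """ML haplotype frequencies for two loci from unphased dosage vectors.

    Individuals with a missing call at either locus are dropped
    (complete-case).  Raises :class:`LDUndefinedError` if either locus is
    monomorphic among the retained individuals.

    The EM starts from linkage equilibrium and iterates until the largest
    frequency change is below ``1e-10`` (at most 1000 iterations); with no
    double heterozygotes the direct haplotype counts are already exact.
    """
    a = np.asarray(genos_a)
    b = np.asarray(genos_b)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must have the same length")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    n = a.size
    if n == 0:
        raise LDUndefinedError("no jointly called individuals")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise LDUndefinedError("LD undefined: monomorphic locus in this sample")

    # 3x3 genotype table, cell (i, j) = count of dosage_a == i and dosage_b == j
    tab = np.zeros((3, 3), dtype=np.int64)
    np.add.at(tab, (a.astype(int), b.astype(int)), 1)

    # Unambiguous haplotype counts.  Dosage counts allele2, so dosage 0 at A
    # means two A1 alleles.  Cell (ia, ib) of the table contributes:
    #   A-alleles: (2-ia) copies of A1, ia copies of A2 (and likewise for B);
    # every cell except (1,1) has a unique phase.
    c11 = 2 * tab[0, 0] + tab[0, 1] + tab[1, 0]
    c12 = 2 * tab[0, 2] + tab[0, 1] + tab[1, 2]
    c21 = 2 * tab[2, 0] + tab[2, 1] + tab[1, 0]
    c22 = 2 * tab[2, 2] + tab[2, 1] + tab[1, 2]
    dh = int(tab[1, 1])  # double heterozygotes: coupling or repulsion
    total = 2.0 * n

    # init at linkage equilibrium
    fA1 = (c11 + c12 + dh) / total
    fB1 = (c11 + c21 + dh) / total
    f11 = fA1 * fB1
    f12 = fA1 * (1 - fB1)
    f21 = (1 - fA1) * fB1
    f22 = (1 - fA1) * (1 - fB1)

    n_iter = 0
    if dh:
        for n_iter in range(1, EM_MAX_ITER + 1):
            coup = f11 * f22
            rep = f12 * f21
            p_coup = coup / (coup + rep) if coup + rep > 0 else 0.5
            g11 = (c11 + dh * p_coup) / total
            g12 = (c12 + dh * (1 - p_coup)) / total
            g21 = (c21 + dh * (1 - p_coup)) / total
            g22 = (c22 + dh * p_coup) / total
            delta = max(
                abs(g11 - f11), abs(g12 - f12), abs(g21 - f21), abs(g22 - f22)
            )
            f11, f12, f21, f22 = g11, g12, g21, g22
            if delta < EM_TOL:
                break
    else:
        f11, f12, f21, f22 = c11 / total, c12 / total, c21 / total, c22 / total

    return HaplotypeFreqs(f11, f12, f21, f22, n_pairs=n, n_iter=n_iter)


def r2_from_freqs(h: HaplotypeFreqs) -> float:
    """Squared allelic correlation r^2 from haplotype frequencies."""
    denom = h.fA1 * h.fA2 * h.fB1 * h.fB2
    if denom <= 0:
        raise LDUndefinedError("LD undefined: an allele frequency is zero")
    d = h.f11 * h.f22 - h.f12 * h.f21
    r2 = d * d / denom
    if r2 > 1.0:
        if r2 > 1.0 + 1e-12:
            raise ValueError(f"r^2 = {r2} exceeds 1 beyond rounding error")
        r2 = 1.0
    return max(r2, 0.0)


def snp_pair_r2(genos_a: np.ndarray, genos_b: np.ndarray) -> float:
    """Convenience: EM haplotype frequencies then r^2 for one SNP pair."""
    return r2_from_freqs(em_haplotype_freqs(genos_a, genos_b))


@dataclass(frozen=True)
class PopulationLD:
    """Mean LD over SNP pairs within one population."""

    mean_r2: float
    se_r2: float
    n_pairs: int
    n_skipped: int  # pairs with undefined r^2 (monomorphic locus)
    pairs: pd.DataFrame  # snp_a, snp_b, bp_distance, r2


def population_mean_ld(
    g: GenotypeMatrix,
    scheme: str = "adjacent",
    window_kb: float | None = None,
) -> PopulationLD:
    """Mean r^2 (+/- SE over pairs) for one population's genotype panel.

    ``scheme="adjacent"`` (default) uses every pair of neighbouring SNPs on
    the same chromosome; ``scheme="window_kb"`` uses every same-chromosome
    pair closer than ``window_kb`` kb.  Pairs where either SNP is monomorphic
    within the population are skipped and counted in ``n_skipped``.
    """
    if scheme not in ("adjacent", "window_kb"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "window_kb" and not window_kb:
        raise ValueError("window_kb scheme requires a window_kb value")
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples for LD")

    records = []
    n_skipped = 0
    for c in g.chroms:
        cols = g.chrom_indices(c)
        bp = g.bp_positions(c)
        if cols.size < 2:
            continue
        if scheme == "adjacent":
            pair_idx = [(k, k + 1) for k in range(cols.size - 1)]
        else:
            pair_idx = [
                (k, l)
                for k in range(cols.size - 1)
                for l in range(k + 1, cols.size)
                if (bp[l] - bp[k]) / 1000.0 <= window_kb
            ]
        for k, l in pair_idx:
            ja, jb = cols[k], cols[l]
            try:
                r2 = snp_pair_r2(g.calls[:, ja], g.calls[:, jb])
            except LDUndefinedError:
                n_skipped += 1
                continue
            records.append(
                {
                    "snp_a": g.snps[ja].snp_id,
                    "snp_b": g.snps[jb].snp_id,
                    "bp_distance": int(bp[l] - bp[k]),
                    "r2": r2,
                }
            )
    if not records:
        raise LDUndefinedError("no SNP pair with defined r^2 in this population")
    pairs = pd.DataFrame.from_records(records)
    r2s = pairs["r2"].to_numpy()
    se = float(r2s.std(ddof=1) / np.sqrt(r2s.size)) if r2s.size > 1 else 0.0
    return PopulationLD(
        mean_r2=float(r2s.mean()),
        se_r2=se,
        n_pairs=len(records),
        n_skipped=n_skipped,
        pairs=pairs,
    )
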