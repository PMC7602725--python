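"""SNP-level quality control: minor allele frequency, exact Hardy–Weinberg
equilibrium, and call rate.

A SNP is *removed* when any of the three statistics falls at or below its
threshold (the boundary is inclusive):

* minor allele frequency <= 0.05,
* exact HWE p-value <= 1e-4,
* call rate <= 0.95.

Note the inclusive boundary deliberately follows the screening protocol's
wording rather than PLINK's ``--maf``/``--geno`` conventions (which remove at
strictly-below / missing-rate-above thresholds).

The HWE test is the standard exact conditional test on genotype counts
(Wigginton, Cutler & Abecasis style): given the observed allele counts, the
two-sided p-value sums the probabilities of all heterozygote counts whose
conditional probability does not exceed that of the observed count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

# Relative guard when comparing tail probabilities to the observed one, so
# that mathematically tied configurations are included despite rounding.
_HWE_TIE_REL = 1e-12


@dataclass(frozen=True)
class QCThresholds:
    """Removal thresholds; a SNP at or below any of them is dropped."""

    maf_max_removed: float = 0.05
    hwe_p_max_removed: float = 1e-4
    callrate_max_removed: float = 0.95

    def __post_init__(self):
        for name in ("maf_max_removed", "hwe_p_max_removed", "callrate_max_removed"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QCReport:
    """Per-SNP QC statistics and removal flags.

    ``table`` has one row per input SNP with columns ``snp_id``, ``maf``,
    ``hwe_p``, ``call_rate`` and ``removed_by`` (comma-joined subset of
    ``{MAF, HWE, CALLRATE}``, empty when retained).
    """

    table: pd.DataFrame
    n_input: int
    n_retained: int
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def allele_frequency(calls_at_snp: np.ndarray) -> tuple[float, float]:
    """Allele2 frequency and minor allele frequency over non-missing calls.

    Returns ``(nan, nan)`` when every call is missing; callers treat an
    undefined MAF as failing the MAF rule.
    """
    calls = np.asarray(calls_at_snp)
    if calls.size == 0:
        raise ValueError("empty call vector")
    ok = calls != MISSING
    n = int(ok.sum())
    if n == 0:
        return float("nan"), float("nan")
    f = float(calls[ok].sum()) / (2 * n)
    return f, min(f, 1.0 - f)


def snp_call_rate(calls_at_snp: np.ndarray) -> float:
    """Fraction of non-missing calls at one SNP."""
    calls = np.asarray(calls_at_snp)
    if calls.size == 0:
        raise ValueError("empty call vector")
    return float((calls != MISSING).mean())


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy–Weinberg test p-value from genotype counts.

    Conditions on the observed allele counts and enumerates the probability
    of every compatible heterozygote count via the standard recurrence; the
    p-value is the summed probability of all configurations no more likely
    than the observed one.  Always in ``(0, 1]``.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("all genotype counts are zero")

    n1 = 2 * n_hom1 + n_het  # allele1 count
    n2 = 2 * n_hom2 + n_het
    rare = min(n1, n2)
    if rare == 0:  # monomorphic: a single configuration
        return 1.0

    # Heterozygote counts share the parity of the rare-allele count.
    het_values = list(range(rare % 2, rare + 1, 2))
    probs = np.zeros(len(het_values))
    # start from the modal het count and fill outward with the recurrence
    mid = int(round(rare * (2 * n - rare) / (2.0 * n)))
    if mid % 2 != rare % 2:
        mid += 1 if mid < rare else -1
    mid_idx = het_values.index(mid)
    probs[mid_idx] = 1.0
    # going down: P(h-2)/P(h) = h(h-1) / ((r-h+2)/2 * ... ) expressed via
    # hom counts: hom_r = (rare-h)/2, hom_c = (2n-rare-h)/2
    for idx in range(mid_idx, 0, -1):
        h = het_values[idx]
        hom_r = (rare - h) / 2.0
        hom_c = (2 * n - rare - h) / 2.0
        probs[idx - 1] = probs[idx] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
    for idx in range(mid_idx, len(het_values) - 1):
        h = het_values[idx]
        hom_r = (rare - h) / 2.0
        hom_c = (2 * n - rare - h) / 2.0
        probs[idx + 1] = probs[idx] * 4.0 * hom_r * hom_c / ((h + 1) * (h + 2))
    probs /= probs.sum()

    p_obs = probs[het_values.index(n_het)]
    p = float(probs[probs <= p_obs * (1.0 + _HWE_TIE_REL)].sum())
    return min(p, 1.0)


def _genotype_counts(calls: np.ndarray) -> tuple[int, int, int]:
    return (
        int((calls == 0).sum()),
        int((calls == 1).sum()),
        int((calls == 2).sum()),
    )


def apply_qc(
    g: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    hwe_scope: str = "pooled",
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter SNPs by the MAF / HWE / call-rate rules.

    Parameters
    ----------
    g:
        Input genotypes (any number of populations).
    thresholds:
        Removal thresholds; defaults to ``QCThresholds()``.
    hwe_scope:
        ``"pooled"`` (default) tests HWE on all samples together;
        ``"per_population"`` tests within each population and removes a SNP
        if *any* population is out of equilibrium at the threshold.

    Returns the filtered matrix (SNP order preserved) and a :class:`QCReport`.
    Filtering is idempotent: re-applying the same thresholds to the output
    removes nothing.
    """
    if g.n_snps == 0 or g.n_samples == 0:
        raise ValueError("cannot QC an empty genotype matrix")
    t = thresholds or QCThresholds()
    if hwe_scope not in ("pooled", "per_population"):
        raise ValueError(f"unknown hwe_scope {hwe_scope!r}")

    pops = np.asarray(g.populations)
    pop_rows = {p: np.flatnonzero(pops == p) for p in dict.fromkeys(g.populations)}

    records = []
    keep_ids = []
    for j, snp in enumerate(g.snps):
        col = g.calls[:, j]
        f2, maf = allele_frequency(col)
        rate = snp_call_rate(col)
        if hwe_scope == "pooled":
            nonmiss = col[col != MISSING]
            hwe_p = (
                hwe_exact_test(*_genotype_counts(nonmiss)) if nonmiss.size else 1.0
            )
        else:
            # minimum p over populations: a SNP out of equilibrium in any
            # population fails, avoiding Wahlund-effect rejections that pure
            # pooling of differentiated populations would produce
            ps = []
            for rows in pop_rows.values():
                sub = col[rows]
                sub = sub[sub != MISSING]
                if sub.size:
                    ps.append(hwe_exact_test(*_genotype_counts(sub)))
            hwe_p = min(ps) if ps else 1.0

        removed_by = []
        if np.isnan(maf) or maf <= t.maf_max_removed:
            removed_by.append("MAF")
        if hwe_p <= t.hwe_p_max_removed:
            removed_by.append("HWE")
        if rate <= t.callrate_max_removed:
            removed_by.append("CALLRATE")
        records.append(
            {
                "snp_id": snp.snp_id,
                "maf": maf,
                "hwe_p": hwe_p,
                "call_rate": rate,
                "removed_by": ",".join(removed_by),
            }
        )
        if not removed_by:
            keep_ids.append(snp.snp_id)

    table = pd.DataFrame.from_records(records)
    report = QCReport(
        table=table, n_input=g.n_snps, n_retained=len(keep_ids), thresholds=t
    )
    if not keep_ids:
        warnings.warn("QC removed every SNP", stacklevel=2)
    filtered = g.subset(snp_keep=keep_ids)
    return filtered, report
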