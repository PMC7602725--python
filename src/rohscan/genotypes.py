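"""In-memory model for diploid SNP-array genotype panels.

The central container is :class:`GenotypeMatrix`: a samples x SNPs matrix of
allele2 dosages (0, 1, 2, or :data:`MISSING`) together with a marker map
(:class:`SNPRecord`) and per-sample metadata (:class:`Sample`).  Every other
stage of the pipeline — QC, ROH calling, LD, population structure — consumes
this one object.

Conventions
-----------
* Dosage counts copies of ``allele2``, the second allele column of a
  MAP/BIM-style map.  No frequency-based re-polarisation is performed, so
  file round-trips are exact.
* Physical positions are 1-based base pairs; lengths downstream are reported
  in kb as ``(end_bp - start_bp) / 1000``.
* Chromosome labels are strings.  Which labels count as autosomes is a
  parameter of the analyses (default ``"1"``–``"28"``, the chicken
  autosomes), never hard-coded into the container.
* A sample's population label is taken from the PLINK family-ID column (the
  usual way breed membership is encoded in such files) and must be non-empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

_VALID_CODES = (-1, 0, 1, 2)

#: Default autosome label set (chicken: 28 autosomes on the 60K chip).
DEFAULT_AUTOSOMES: frozenset[str] = frozenset(str(c) for c in range(1, 29))


def chrom_sort_key(chrom: str):
    """Sort key putting numeric chromosome labels first, in numeric order."""
    try:
        return (0, int(chrom), "")
    except (TypeError, ValueError):
        return (1, 0, str(chrom))


@dataclass(frozen=True)
class SNPRecord:
    """One marker of the map: chromosome, identifiers, position, alleles.

    ``allele1``/``allele2`` are single-token allele codes (e.g. ``A``/``B`` or
    nucleotide letters); ``0`` marks an unobserved allele at a monomorphic
    marker.  ``genetic_pos`` is in cM and may be 0 when no genetic map exists.
    """

    chrom: str
    snp_id: str
    genetic_pos: float
    bp_pos: int
    allele1: str
    allele2: str

    def __post_init__(self):
        if self.bp_pos <= 0:
            raise ValueError(
                f"SNP {self.snp_id}: bp_pos must be positive, got {self.bp_pos}"
            )


@dataclass(frozen=True)
class Sample:
    """One genotyped individual.  ``sex`` follows PLINK: 0 unknown, 1 male, 2 female."""

    sample_id: str
    population: str
    sex: int = 0


class GenotypeMatrix:
    """Samples x SNPs diploid dosage matrix with marker map and labels.

    Parameters
    ----------
    samples:
        Sequence of :class:`Sample`; every ``population`` must be non-empty.
    snps:
        Sequence of :class:`SNPRecord`.  Within each chromosome, positions
        must be strictly increasing in the order given (use
        :meth:`sorted_by_position` after assembling from unsorted sources).
    calls:
        ``(n_samples, n_snps)`` integer array of allele2 dosages with values
        in ``{0, 1, 2, MISSING}``.
    """

    def __init__(
        self,
        samples: Sequence[Sample],
        snps: Sequence[SNPRecord],
        calls: np.ndarray,
        *,
        validate: bool = True,
    ):
        self.samples = list(samples)
        self.snps = list(snps)
        self.calls = np.asarray(calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        if validate:
            self._validate()

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        ns, nv = self.calls.shape
        if ns != len(self.samples) or nv != len(self.snps):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.calls, _VALID_CODES)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.calls[i, j]} at sample "
                f"{self.samples[i].sample_id}, SNP {self.snps[j].snp_id}"
            )
        for s in self.samples:
            if not s.population:
                raise ValueError(f"sample {s.sample_id} has an empty population label")
        seen_ids = set()
        for s in self.samples:
            if s.sample_id in seen_ids:
                raise ValueError(f"duplicate sample id {s.sample_id}")
            seen_ids.add(s.sample_id)
        last_bp: dict[str, int] = {}
        for rec in self.snps:
            prev = last_bp.get(rec.chrom)
            if prev is not None and rec.bp_pos <= prev:
                raise ValueError(
                    f"SNP {rec.snp_id}: positions on chromosome {rec.chrom} "
                    "are not strictly increasing"
                )
            last_bp[rec.chrom] = rec.bp_pos

    # -- basic accessors ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def populations(self) -> list[str]:
        return [s.population for s in self.samples]

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.snps]

    @property
    def chroms(self) -> list[str]:
        """Distinct chromosome labels in map order."""
        seen: dict[str, None] = {}
        for v in self.snps:
            seen.setdefault(v.chrom, None)
        return list(seen)

    def chrom_indices(self, chrom: str) -> np.ndarray:
        """Column indices of the SNPs on ``chrom``, in map order."""
        return np.array([j for j, v in enumerate(self.snps) if v.chrom == chrom], dtype=int)

    def bp_positions(self, chrom: str) -> np.ndarray:
        return np.array([v.bp_pos for v in self.snps if v.chrom == chrom], dtype=np.int64)

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.snps],
                "snp_id": [v.snp_id for v in self.snps],
                "genetic_pos": [v.genetic_pos for v in self.snps],
                "bp_pos": [v.bp_pos for v in self.snps],
                "allele1": [v.allele1 for v in self.snps],
                "allele2": [v.allele2 for v in self.snps],
            }
        )

    def population_map(self) -> dict[str, str]:
        return {s.sample_id: s.population for s in self.samples}

    # -- transformations ----------------------------------------------------
    def sorted_by_position(self) -> "GenotypeMatrix":
        """Return a copy with SNPs sorted by (chromosome, bp position)."""
        order = sorted(
            range(len(self.snps)),
            key=lambda j: (chrom_sort_key(self.snps[j].chrom), self.snps[j].bp_pos),
        )
        return GenotypeMatrix(
            self.samples,
            [self.snps[j] for j in order],
            self.calls[:, order],
        )

    def subset(
        self,
        sample_keep: Iterable[str] | None = None,
        snp_keep: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        """Restrict to the given sample/SNP ids, preserving current order.

        ``None`` keeps everything on that axis.  Unknown ids raise a
        ``KeyError`` listing all of them.
        """
        if sample_keep is None:
            rows = np.arange(self.n_samples)
        else:
            keep = set(sample_keep)
            missing = keep - set(self.sample_ids)
            if missing:
                raise KeyError(f"unknown sample ids: {sorted(missing)}")
            rows = np.array(
                [i for i, s in enumerate(self.samples) if s.sample_id in keep],
                dtype=int,
            )
        if snp_keep is None:
            cols = np.arange(self.n_snps)
        else:
            keep = set(snp_keep)
            missing = keep - set(self.snp_ids)
            if missing:
                raise KeyError(f"unknown SNP ids: {sorted(missing)}")
            cols = np.array(
                [j for j, v in enumerate(self.snps) if v.snp_id in keep], dtype=int
            )
        return GenotypeMatrix(
            [self.samples[i] for i in rows],
            [self.snps[j] for j in cols],
            self.calls[np.ix_(rows, cols)],
            validate=False,
        )

    def restrict_chroms(self, keep: Iterable[str]) -> "GenotypeMatrix":
        """Keep only SNPs on the given chromosome labels (e.g. the autosomes)."""
        keep = set(keep)
        ids = [v.snp_id for v in self.snps if v.chrom in keep]
        return self.subset(snp_keep=ids)

    # -- comparisons --------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.snps == other.snps
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        npop = len(set(self.populations))
        return (
            f"GenotypeMatrix({self.n_samples} samples, {self.n_snps} SNPs, "
            f"{npop} populations)"
        )
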