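"""Sliding-window detection of runs of homozygosity (ROH) and the ROH-based
inbreeding coefficient F_ROH.

Algorithm
---------
The caller mirrors the PLINK ``--homozyg`` scheme.  Per sample and
chromosome:

1. every window of ``window_snps`` consecutive markers is labelled
   *homozygous* iff it contains at most ``window_max_het`` heterozygous and
   at most ``window_max_missing`` missing calls;
2. each SNP's hit rate is the fraction of windows containing it that are
   homozygous; the SNP is *flagged* when the hit rate reaches
   ``window_hit_threshold``;
3. maximal runs of consecutively flagged SNPs are split wherever two
   adjacent flagged SNPs lie more than ``max_gap_kb`` apart, then a run is
   kept as a ROH iff it has at least ``min_snps`` SNPs, spans at least
   ``min_length_kb`` kb, and averages at most ``min_density_kb_per_snp`` kb
   per SNP.

Segment endpoints are the first and last flagged SNP positions and lengths
are ``(end_bp - start_bp) / 1000`` kb.

F_ROH for a sample is the summed ROH length divided by ``L``, the autosomal
genome length covered by SNPs (per chromosome, last minus first marker
position on the working map).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

_EPS_KB = 1e-9  # guard for >=/<= comparisons on kb lengths


@dataclass(frozen=True)
class ROHParams:
    """ROH-calling parameters.

    The window geometry (50 SNPs, <=1 het), the 100-SNP and 1000-kb segment
    minima and the 1-SNP-per-50-kb density rule are the screening protocol's
    settings; the remaining knobs (missing calls per window, window hit
    threshold, maximum within-run gap) default to PLINK 1.9's defaults.
    """

    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 5
    window_hit_threshold: float = 0.05
    min_snps: int = 100
    min_length_kb: float = 1000.0
    min_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0

    def __post_init__(self):
        if self.window_snps <= 0 or self.min_snps <= 0:
            raise ValueError("window_snps and min_snps must be positive")
        if self.window_max_het >= self.window_snps:
            raise ValueError("window_max_het must be smaller than window_snps")
        if min(self.min_length_kb, self.min_density_kb_per_snp, self.max_gap_kb) <= 0:
            raise ValueError("length parameters must be positive")
        if not (0 < self.window_hit_threshold <= 1):
            raise ValueError("window_hit_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class ROHSegment:
    """One called run of homozygosity."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


@dataclass(frozen=True)
class FrohResult:
    """Per-sample ROH summary: count ``k``, summed length, and F_ROH."""

    sample_id: str
    k: int
    total_roh_kb: float
    L_kb: float
    froh: float


def window_scan(sample_calls: np.ndarray, params: ROHParams | None = None) -> np.ndarray:
    """Per-SNP homozygosity flags for one sample on one chromosome.

    ``sample_calls`` must be the dosage vector of consecutive, position-sorted
    SNPs of a single chromosome.  Chromosomes shorter than one window fall
    back to direct per-call homozygosity (a SNP is flagged iff its call is a
    non-missing homozygote).
    """
    p = params or ROHParams()
    calls = np.asarray(sample_calls)
    n = calls.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    het = calls == 1
    miss = calls == MISSING
    w = p.window_snps
    if n < w:
        return ~(het | miss)

    het_c = np.concatenate([[0], np.cumsum(het)])
    miss_c = np.concatenate([[0], np.cumsum(miss)])
    n_win = n - w + 1
    starts = np.arange(n_win)
    win_ok = (het_c[starts + w] - het_c[starts] <= p.window_max_het) & (
        miss_c[starts + w] - miss_c[starts] <= p.window_max_missing
    )

    # windows covering SNP j start in [j-w+1, j] clipped to [0, n_win-1]
    ok_c = np.concatenate([[0], np.cumsum(win_ok)])
    j = np.arange(n)
    lo = np.clip(j - w + 1, 0, n_win - 1)
    hi = np.minimum(j, n_win - 1)
    n_hits = ok_c[hi + 1] - ok_c[lo]
    n_windows = hi - lo + 1
    return (n_hits / n_windows) >= p.window_hit_threshold


def _runs_of_true(flags: np.ndarray):
    """Yield (start_idx, end_idx) of maximal True runs, end inclusive."""
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        yield int(idx[s]), int(idx[e])


def call_roh(g: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHSegment]:
    """Call ROH segments for every sample of a (QC-filtered, autosomal) panel."""
    p = params or ROHParams()
    segments: list[ROHSegment] = []
    chrom_cols = {c: g.chrom_indices(c) for c in g.chroms}
    chrom_bp = {c: g.bp_positions(c) for c in g.chroms}
    for c, bp in chrom_bp.items():
        if np.any(np.diff(bp) <= 0):
            raise ValueError(f"SNPs on chromosome {c} are not position-sorted")

    for i, sample in enumerate(g.samples):
        for c in g.chroms:
            cols = chrom_cols[c]
            bp = chrom_bp[c]
            flags = window_scan(g.calls[i, cols], p)
            for s, e in _runs_of_true(flags):
                run_bp = bp[s : e + 1]
                # split at gaps between adjacent flagged (= consecutive) SNPs
                gaps = np.diff(run_bp) / 1000.0
                cut = np.flatnonzero(gaps > p.max_gap_kb)
                piece_starts = np.concatenate([[0], cut + 1])
                piece_ends = np.concatenate([cut, [run_bp.size - 1]])
                for ps, pe in zip(piece_starts, piece_ends):
                    n_snps = pe - ps + 1
                    length_kb = (run_bp[pe] - run_bp[ps]) / 1000.0
                    if n_snps < p.min_snps:
                        continue
                    if length_kb < p.min_length_kb - _EPS_KB:
                        continue
                    if length_kb / n_snps > p.min_density_kb_per_snp + _EPS_KB:
                        continue
                    segments.append(
                        ROHSegment(
                            sample_id=sample.sample_id,
                            chrom=c,
                            start_bp=int(run_bp[ps]),
                            end_bp=int(run_bp[pe]),
                            n_snps=n_snps,
                        )
                    )
    return segments


def covered_genome_kb(g: GenotypeMatrix) -> float:
    """SNP-covered genome length ``L`` in kb: sum over chromosomes of
    (last - first marker position)."""
    total = 0.0
    for c in g.chroms:
        bp = g.bp_positions(c)
        if bp.size >= 2:
            total += (bp[-1] - bp[0]) / 1000.0
    return total


def compute_froh(
    segments: list[ROHSegment], g: GenotypeMatrix, sample_id: str | None = None
) -> FrohResult:
    """F_ROH for one sample: summed ROH length over the SNP-covered genome.

    ``segments`` may be the full segment list; when ``sample_id`` is omitted
    all segments must belong to a single sample.
    """
    if sample_id is None:
        owners = {s.sample_id for s in segments}
        if len(owners) > 1:
            raise ValueError("segments belong to several samples; pass sample_id")
        sample_id = owners.pop() if owners else ""
    segs = [s for s in segments if s.sample_id == sample_id]
    L = covered_genome_kb(g)
    if L <= 0:
        raise ValueError("covered genome length is zero; cannot compute F_ROH")
    total = float(sum(s.length_kb for s in segs))
    return FrohResult(
        sample_id=sample_id,
        k=len(segs),
        total_roh_kb=total,
        L_kb=L,
        froh=total / L,
    )


def froh_all_samples(
    segments: list[ROHSegment], g: GenotypeMatrix
) -> list[FrohResult]:
    """F_ROH for every sample in ``g`` (zero segments gives F_ROH = 0)."""
    by_sample: dict[str, list[ROHSegment]] = {sid: [] for sid in g.sample_ids}
    for s in segments:
        by_sample[s.sample_id].append(s)
    return [compute_froh(by_sample[sid], g, sid) for sid in g.sample_ids]


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    """Mean and standard error (sd with n-1 over sqrt(n); SE = 0 when n < 2)."""
    x = np.asarray(x, dtype=float)
    m = float(x.mean())
    se = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return m, se


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """PLINK ``.hom``-style table of called segments."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in segments],
            "chrom": [s.chrom for s in segments],
            "start_bp": [s.start_bp for s in segments],
            "end_bp": [s.end_bp for s in segments],
            "length_kb": [s.length_kb for s in segments],
            "n_snps": [s.n_snps for s in segments],
        }
    )


def froh_to_frame(results: list[FrohResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "n_roh": [r.k for r in results],
            "total_roh_kb": [r.total_roh_kb for r in results],
            "covered_kb": [r.L_kb for r in results],
            "froh": [r.froh for r in results],
        }
    )


def roh_population_summary(
    froh_results: list[FrohResult],
    segments: list[ROHSegment],
    labels: dict[str, str],
    length_metric: str = "mean",
) -> pd.DataFrame:
    """Per-population ROH summary table.

    One row per population with mean +/- SE, min and max of the
    per-individual ROH count; mean +/- SE, min and max of the per-individual
    ROH length (``length_metric="mean"`` averages an individual's segment
    lengths, ``"total"`` sums them; individuals without ROH contribute 0);
    and mean +/- SE of F_ROH.
    """
    if length_metric not in ("mean", "total"):
        raise ValueError("length_metric must be 'mean' or 'total'")
    unlabelled = [r.sample_id for r in froh_results if r.sample_id not in labels]
    if unlabelled:
        raise KeyError(f"samples without population label: {unlabelled}")

    seg_lengths: dict[str, list[float]] = {r.sample_id: [] for r in froh_results}
    for s in segments:
        seg_lengths.setdefault(s.sample_id, []).append(s.length_kb)

    rows = []
    pops = sorted({labels[r.sample_id] for r in froh_results})
    for pop in pops:
        rs = [r for r in froh_results if labels[r.sample_id] == pop]
        counts = np.array([r.k for r in rs], dtype=float)
        if length_metric == "mean":
            lengths = np.array(
                [np.mean(seg_lengths[r.sample_id]) if r.k else 0.0 for r in rs]
            )
        else:
            lengths = np.array([r.total_roh_kb for r in rs])
        frohs = np.array([r.froh for r in rs])
        cm, cse = _mean_se(counts)
        lm, lse = _mean_se(lengths)
        fm, fse = _mean_se(frohs)
        rows.append(
            {
                "population": pop,
                "n": len(rs),
                "roh_count_mean": cm,
                "roh_count_se": cse,
                "roh_count_min": float(counts.min()),
                "roh_count_max": float(counts.max()),
                "roh_length_kb_mean": lm,
                "roh_length_kb_se": lse,
                "roh_length_kb_min": float(lengths.min()),
                "roh_length_kb_max": float(lengths.max()),
                "froh_mean": fm,
                "froh_se": fse,
            }
        )
    return pd.DataFrame(rows)
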