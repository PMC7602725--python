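"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the vectorised/recurrence shortcuts of the package:
the HWE oracle evaluates every heterozygote configuration from the explicit
log-factorial formula, and the ROH oracle enumerates every scan window and
run by direct slicing.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from rohscan.genotypes import MISSING
from rohscan.roh import ROHParams


def hwe_exact_oracle(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Full-enumeration exact HWE p-value via the closed-form conditional
    probability of each heterozygote count."""
    n = n_hom1 + n_het + n_hom2
    n1 = 2 * n_hom1 + n_het
    n2 = 2 * n_hom2 + n_het
    rare = min(n1, n2)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = (2 * n - rare - hets) // 2
    # log P(h | n1, n2) up to a constant:
    #   n! 2^h / (hom_r! h! hom_c!) * n1! n2! / (2n)!
    logp = hets * np.log(2.0) - (
        gammaln(hom_r + 1) + gammaln(hets + 1) + gammaln(hom_c + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[list(hets).index(n_het)]
    return float(min(p[p <= p_obs * (1.0 + 1e-12)].sum(), 1.0))


def window_flags_oracle(calls, p: ROHParams) -> list[bool]:
    """Per-SNP homozygosity flags by explicit enumeration of every window."""
    calls = list(calls)
    n = len(calls)
    het = [c == 1 for c in calls]
    miss = [c == MISSING for c in calls]
    w = p.window_snps
    if n < w:
        return [not h and not m for h, m in zip(het, miss)]
    ok = [
        sum(het[s : s + w]) <= p.window_max_het
        and sum(miss[s : s + w]) <= p.window_max_missing
        for s in range(n - w + 1)
    ]
    flags = []
    for j in range(n):
        lo = max(0, j - w + 1)
        hi = min(j, n - w)
        wins = ok[lo : hi + 1]
        flags.append(sum(wins) / len(wins) >= p.window_hit_threshold)
    return flags


def call_roh_oracle(calls, bp, p: ROHParams):
    """ROH segments for one sample/chromosome as (start_idx, end_idx, n_snps,
    length_kb) tuples, by direct run enumeration."""
    flags = window_flags_oracle(calls, p)
    n = len(flags)
    segs = []
    i = 0
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flags[j + 1]:
            j += 1
        # split the run at large gaps
        pieces = [[i]]
        for k in range(i + 1, j + 1):
            if (bp[k] - bp[k - 1]) / 1000.0 > p.max_gap_kb:
                pieces.append([k])
            else:
                pieces[-1].append(k)
        for piece in pieces:
            a, b = piece[0], piece[-1]
            ns = b - a + 1
            ln = (bp[b] - bp[a]) / 1000.0
            if (
                ns >= p.min_snps
                and ln >= p.min_length_kb - 1e-9
                and ln / ns <= p.min_density_kb_per_snp + 1e-9
            ):
                segs.append((a, b, ns, ln))
        i = j + 1
    return segs


def random_roh_chromosome(rng: np.random.Generator, n_snps: int):
    """A synthetic single-sample chromosome with alternating autozygous and
    outbred stretches, plus genotyping noise, for oracle comparisons."""
    calls = np.empty(n_snps, dtype=np.int8)
    pos = 0
    while pos < n_snps:
        seg_len = min(n_snps - pos, 1 + rng.geometric(1.0 / 120.0))
        if rng.random() < 0.5:  # autozygous stretch: rare het/missing noise
            block = rng.choice([0, 2], size=seg_len)
            noise = rng.random(seg_len)
            block[noise < 0.01] = 1
            block[(noise >= 0.01) & (noise < 0.03)] = MISSING
        else:  # outbred stretch
            block = rng.choice([0, 1, 2, MISSING], size=seg_len,
                               p=[0.3, 0.38, 0.3, 0.02])
        calls[pos : pos + seg_len] = block
        pos += seg_len
    spacing = rng.choice([5_000, 10_000, 25_000, 60_000, 1_200_000],
                         size=n_snps, p=[0.25, 0.3, 0.3, 0.13, 0.02])
    bp = np.cumsum(spacing) + 1
    return calls, bp
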