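from __future__ import annotations

import numpy as np
import pytest

import rohscan as rs


def make_matrix(
    calls,
    chroms=None,
    bp=None,
    populations=None,
    allele1="A",
    allele2="B",
) -> rs.GenotypeMatrix:
    """Build a GenotypeMatrix from a dosage array with simple defaults."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    chroms = list(chroms) if chroms is not None else ["1"] * m
    bp = list(bp) if bp is not None else None
    if bp is None:
        bp, counter = [], {}
        for c in chroms:
            counter[c] = counter.get(c, 0) + 1
            bp.append(counter[c] * 1000)
    populations = populations or ["POP"] * n
    samples = [
        rs.Sample(sample_id=f"S{i + 1}", population=populations[i])
        for i in range(n)
    ]
    snps = [
        rs.SNPRecord(
            chrom=str(chroms[j]),
            snp_id=f"m{j + 1}",
            genetic_pos=0.0,
            bp_pos=int(bp[j]),
            allele1=allele1,
            allele2=allele2,
        )
        for j in range(m)
    ]
    return rs.GenotypeMatrix(samples, snps, calls)


@pytest.fixture(scope="session")
def default_panel():
    """The default simulated germplasm panel (4 breeds, 3 crosses), seed 1."""
    return rs.simulate_panel(rs.default_scenario(seed=1))


@pytest.fixture(scope="session")
def default_panel_roh(default_panel):
    g, truth = default_panel
    segments = rs.call_roh(g)
    froh = rs.froh_all_samples(segments, g)
    return g, truth, segments, froh
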