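"""SNP quality control and per-population linkage disequilibrium.

QC removes SNPs with minor allele frequency <= 0.05, exact Hardy-Weinberg
p <= 1e-4, or call rate <= 95% (all boundaries inclusive).  LD is the mean
r^2 over adjacent same-chromosome SNP pairs, estimated from EM haplotype
frequencies; drifted closed lines show much higher background LD than
crosses.
"""

import rohscan as rs

g, _ = rs.simulate_panel(rs.default_scenario(seed=1))
filtered, report = rs.apply_qc(g)
print(
    f"QC: {report.n_retained} of {report.n_input} SNPs retained "
    f"(pooled samples; removals are dominated by SNPs drifted to MAF <= 0.05)"
)

for pop in ("BR1", "BR1xBR2"):
    sub = filtered.subset(
        sample_keep=[s.sample_id for s in filtered.samples if s.population == pop]
    )
    ld = rs.population_mean_ld(sub, scheme="adjacent")
    print(
        f"{pop:10s} mean adjacent-pair r^2 = {ld.mean_r2:.3f} +/- {ld.se_r2:.3f} "
        f"({ld.n_pairs} pairs, {ld.n_skipped} monomorphic pairs skipped)"
    )
print(
    "\nThe purebred line's stronger drift produces higher r^2 between"
    "\nneighbouring markers than in its F1 cross."
)
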