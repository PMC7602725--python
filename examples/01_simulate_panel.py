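"""Simulate a germplasm-collection-like SNP panel and write PLINK files.

Four small closed purebred lines (4 founders, census 20, 20 closed
generations) plus two two-way F1 crosses and one three-way F1 cross, on a
5-chromosome, ~10k-SNP chip-like map.  The truth table records, per bird,
the pedigree inbreeding coefficient F (expected autozygosity from the
pedigree), the realised autozygosity (known exactly from tracked founder
haplotypes), and the breed-of-origin fractions.
"""

import rohscan as rs

scenario = rs.default_scenario(seed=1)
g, truth = rs.simulate_panel(scenario, out_prefix="scratch_panel")

print(g)
print("\nMean inbreeding per population (pedigree F vs realised autozygosity):")
print(
    truth.groupby("population")[["f_pedigree", "f_realized"]]
    .mean()
    .round(3)
    .to_string()
)
print(
    "\nPurebred lines accumulate F ~ 0.4 after 20 closed generations at"
    "\ncensus 20; F1 crosses between independently founded lines have F = 0."
    "\nFiles written: scratch_panel.ped/.map and scratch_panel.truth.tsv"
)
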