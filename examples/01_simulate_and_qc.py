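"""Simulate a goat population and run SNP quality control.

Draws 300 goats x 2,000 HWE markers with the default three-trait udder
architecture plus 2% missing calls, then applies the marker filters
(call rate >= 0.90, non-monomorphic, MAF >= 0.05, HWE deviation <= 0.15)
and the sample call-rate filter, printing the per-filter exclusion counts.
"""

from caprigen import SimConfig, sample_qc, simulate_genotypes, variant_qc

cfg = SimConfig(n_individuals=300, n_markers=2000, n_causal=200,
                missing_rate=0.02, seed=7)
genos = simulate_genotypes(cfg)
print(f"simulated {genos.n_samples} goats x {genos.n_markers} markers, "
      f"{genos.missing.mean():.1%} missing calls\n")

genos, vrep = variant_qc(genos)
print(vrep)
genos, srep = sample_qc(genos)
print(f"sample call-rate filter: {srep.removed_sample_call_rate} of "
      f"{srep.n_input_samples} goats removed")
# Markers drawn near the MAF bound fall under 0.05 by sampling noise, so a
# small MAF exclusion count is expected; HWE removals should be rare because
# genotypes were drawn exactly at Hardy-Weinberg proportions.
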