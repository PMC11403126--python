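"""Apply the SNP filter cascade to a simulated VCF.

Shows the per-step removal report for the juvenile regime: site QUAL,
minor allele count, depth masks (3/7/20 reads), 75% call rate, excess
heterozygosity, allele balance, one SNP per RAD tag, and the regime's
individual-missingness and MAF screens.
"""

import kinbreed as kb

cfg = kb.load_scenario("hotel1_like")
cfg.seed = 7
cfg.snps_per_tag = 2  # two SNPs per RAD tag so the one-per-tag rule bites
_, _, obs_gm, _ = kb.simulate_dataset(cfg)

filtered, report = kb.filter_cascade(obs_gm, regime="juvenile")

print(report.as_frame().to_string(index=False))
print(f"\n{report.input_shape[1]} loci x {report.input_shape[0]} individuals "
      f"-> {report.output_shape[1]} loci x {report.output_shape[0]} individuals")
# Each row is one screen; sites_removed / calls_masked say what that rule
# cost.  The surviving panel satisfies every screen simultaneously.
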