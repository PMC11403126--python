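"""Simulate a two-cohort crayfish-like breeding system and write its
VCF, metadata, and true pedigree.

The bundled "hotel1_like" scenario breeds 50 females and 50 males over
two cohorts with 20% breeder carryover, genotypes everyone at 930 SNPs,
and overlays 1% per-allele genotyping error plus depth-driven
missingness.
"""

from pathlib import Path

import kinbreed as kb

out = Path("scratch/example_sim")
out.mkdir(parents=True, exist_ok=True)

cfg = kb.load_scenario("hotel1_like")
cfg.seed = 7
ped, true_gm, obs_gm, meta = kb.simulate_dataset(cfg)

kb.write_vcf(obs_gm, out / "observed.vcf")
kb.write_metadata(meta, out / "metadata.csv")
kb.write_pedigree(ped, out / "true_pedigree.csv")

n_juv = (meta["stage"] == "juvenile").sum()
print(f"pedigree: {ped.n_offspring} offspring from "
      f"{len(ped.contributing_parents())} contributing parents "
      f"over {cfg.n_cohorts} cohorts")
print(f"observed matrix: {obs_gm.n_individuals} individuals x "
      f"{obs_gm.n_loci} loci, "
      f"{(obs_gm.dosage == kb.MISSING).mean():.1%} missing calls")
print(f"metadata: {n_juv} juveniles sampled (carapace < 20 mm)")
print(f"files in {out}/")
# The true pedigree is the ground truth every downstream example is
# checked against; the observed VCF is what a field study would start from.
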