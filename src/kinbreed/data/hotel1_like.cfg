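# Two-cohort retention-pond scenario: fall cohort plus a post-treatment
# summer cohort, 20% breeder carryover, 930-SNP one-per-tag panel.
n_males = 50
n_females = 50
n_loci = 930
maf_range = 0.05,0.5
mean_mates_per_female = 2.8
male_skew_concentration = 0.5
clutch_size_mean = 8.0
clutch_size_dispersion = 2.0
n_cohorts = 2
parent_carryover_prob = 0.2
error_rate = 0.01
mean_depth = 28.0
depth_dispersion = 15.0
missing_rate = 0.02
qual_fail_rate = 0.02
growth_intercept_mm = 5.0
growth_rate_mm_per_day = 0.05
growth_sd_mm = 2.0
snps_per_tag = 1
n_chromosomes = 94
waterbody = Hotel1-like
birth_date0 = 2020-09-01
cohort_spacing_days = 300
seed = 0
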