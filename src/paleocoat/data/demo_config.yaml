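# Demo pipeline configuration: simulate a small cohort at study-like depth and
# run genotyping, damage profiling, authentication and phenotype inference.
scenario: packaged:demo_scenario.tsv
seed: 20131002
n_replicates: 3
reads_per_replicate: 422
deamination_rate: 0.02
base_error_rate: 0.002
allele_bias: 0.5
threshold_hom_ref: 0.10
threshold_het_low: 0.25
threshold_het_high: 0.75
min_replicates: 2
alpha: 0.05
concordance_tol: 0.25
write_reads: false
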