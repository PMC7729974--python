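"""Generate a synthetic two-fluid cohort and apply the 50% frequency filter.

A peptide counts as present in a fluid when it is detected in at least half
of that fluid's samples within at least one gestational-age bin.
"""

from amniopep import SimulationConfig, frequency_filter, generate_cohort

config = SimulationConfig(
    n_peptides_shared=200,
    n_peptides_af_only=80,
    n_peptides_fu_only=120,
    n_af_samples=60,
    n_fu_samples=30,
    n_paired=16,
    corr_subset_size=40,
    seed=42,
)
cohort = generate_cohort(config)
samples = cohort.samples
print(f"catalog: {len(cohort.catalog)} peptides; "
      f"{samples.fluid.eq('AF').sum()} AF and {samples.fluid.eq('FU').sum()} FU samples")

af = frequency_filter(cohort.af, samples[samples.fluid == "AF"], min_freq=0.5)
fu = frequency_filter(cohort.fu, samples[samples.fluid == "FU"], min_freq=0.5)
print(f"AF peptidome after filtering: {af.shape[1]} peptides "
      f"(of {cohort.af.shape[1]} catalog entries)")
print(f"FU peptidome after filtering: {fu.shape[1]} peptides")
# with detection probabilities < 1, rarely detected peptides drop out here;
# the filtered column sets are what the overlap analysis compares
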