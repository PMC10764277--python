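"""Generate a synthetic microbiome study with known ground truth.

Builds a clade-structured reference pangenome (role-labelled proteins,
pathway definitions, a binary phenotype matrix) and a two-arm longitudinal
cohort (DNA abundances in TPM, negative-binomial transcript counts, WLZ
trajectories with planted MAG effects)."""

from magpheno import synthdata as sd

config = sd.SimulationConfig(n_ref_genomes=30, n_phenotypes=10,
                             n_participants=24, seed=42)
pangenome = sd.generate_reference_collection(config)
cohort = sd.simulate_cohort(pangenome, config)

print(f"reference genomes : {len(pangenome.genomes)}")
print(f"phenotypes        : {pangenome.truth_bpm.shape[1]} "
      f"(prevalence {pangenome.truth_bpm.mean().min():.2f}-"
      f"{pangenome.truth_bpm.mean().max():.2f})")
print(f"functional roles  : {len(pangenome.all_roles())}")
print(f"cohort            : {cohort.meta['PID'].nunique()} participants x "
      f"{cohort.meta['study_week'].nunique()} weeks = {len(cohort.meta)} samples")
print(f"transcripts       : {cohort.transcript_counts.shape[0]} genes")
planted = {m: b for m, b in cohort.truth_effects['wlz_beta1'].items() if b != 0}
print(f"planted WLZ effects: {planted}")
# The BPM is exact by construction: a genome scores 1 for a phenotype iff it
# carries every role of some pathway variant, so downstream predictions can
# be scored against it.
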