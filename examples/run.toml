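# Complete example run configuration for the `conformity` command-line
# tools.  Every key is optional; omitted keys take the defaults shown
# here.  Unknown keys are rejected.

# Where `conformity simulate` / `conformity sweep` write their outputs
# unless --out overrides it.
output_dir = "."
log_level = "INFO"

[simulation]
n_subpops = 20        # number of subpopulations (island model)
subpop_size = 50      # individuals per subpopulation (even; half male, half female)
beta = 2.8            # conformity strength of the logistic learning rule
d = 0.02              # offspring dispersal fraction per generation
r = 0.20              # recombination rate between display and strategy loci
q0 = 0.20             # initial frequency of the conformity allele C
alpha = 0.0           # choice error rate (uniform-random choice probability)
generations = 500     # fixed horizon; runs continue past fixation
perception = "male-frequency"   # or "mating-observation"
seed = 0              # master seed; sweeps derive per-replicate streams

[sweep]
# grids for `conformity sweep`: every (beta, d) cell is run `replicates`
# times with independent, reproducible seeds
betas = [1.0, 2.0, 2.8, 4.0]
ds = [0.02, 0.1, 0.4, 0.8]
replicates = 20

[estimator]
weighting = "binomial"   # "binomial" (inverse-variance) or "ols"
unanimity = "haldane"    # "haldane" continuity correction or "drop"
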