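# Full two-site analysis at the study scale (simulated data).
# Omit any key to use its default; set `observations:` to a CSV path to
# analyze real trial data instead of simulating.
sites: [HiProd, LoProd]
traits: [HT, M_D13C, PI_D13C, SLA, DW, PGI]
fitness_trait: HT
n_boot: 1000        # FST locus bootstrap iterations
n_perm: 999         # integration randomization / permutation count
seed: 1
out_dir: results
# per-site overrides of the simulation defaults, e.g.:
# sim:
#   LoProd: {families_per_population: 4}
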