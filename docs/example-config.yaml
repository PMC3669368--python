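# Example configuration for `genepower run`.
# Either name one of the built-in study grids ...
grid: no_ld            # no_ld | causal_ld | causal_ld_tagonly | noncausal_ld
replicates: 100        # case-control samples per setting (study scale: 500)
alpha: 0.05
vegas_sims: 1000
base_seed: 1
workers: 1

# ... or comment out `grid` and list explicit settings instead:
# settings:
#   - {setting_id: demo, n_causal: 1, n_noncausal: 4, rr: 2.0,
#      n_total: 2000, maf_causal: 0.30, maf_noncausal: 0.30}
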