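# End-to-end recovery experiment for `liverkin recover`.
# Small sizes keep the run to a couple of minutes; raise n_per_group
# and n_starts for tighter Monte-Carlo error.
n_per_group: 3
noise_cv: 0.05
seed: 1
n_starts: 4
protocols: [short_term, full_dynamic]
models: [three_compartment, combined]
out_dir: recovery_report
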