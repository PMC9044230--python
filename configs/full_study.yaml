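# Full factorial study design: 3 structures x 3 scenarios x 27 sample
# sizes, 10 replicates, all five reducers.  Identical to running
# `psychae run-grid` with no config.  Expect hours of CPU time at this
# scale; override `replicates` or `sample_sizes` for desk-scale runs.
structures: [high, wide, low]
scenarios: [s1, s2, s3]
sample_sizes: [100, 110, 120, 130, 140, 150, 160, 170, 180, 190,
               200, 250, 300, 350, 400, 450, 500, 550, 600, 650,
               700, 750, 800, 850, 900, 950, 1000]
replicates: 10
train_fraction: 0.8
master_seed: 20210
algorithms: [pca, simple_ae, tied_ae, deep_ae, independent_ae]
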