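# Demo configuration for the full pipeline (cytoferm run --config configs/demo.yaml).
# One seed governs every stochastic component.
seed: 7
outdir: results/demo

# gating cut-offs are strain/instrument specific and therefore required
width_cutoff: 80
fl1_cutoff: 100
fsc_threshold: 80000
max_events: 10000
n_events: 3000
n_timepoints: 5
n_replicates: 4
groups: [I, II, III]

# weak-acid partitioning (pyruvate)
pka: 2.5
ph_out: 5.0
ph_in_starved: 6.0
ph_in_growth: 7.0
mw: 88.06

# yields
ba0_mm: 5.0
yield_basis: initial
producer_variants:
  1x: 1.1
  6x_alt1d: 2.0
  7x_alt1d: 2.9

# statistics
stats_method: mannwhitney
stats_direction: x
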