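# cytoferm

Analytics for yeast whole-cell biocatalysis studies that track a
culture with flow cytometry while it converts a ketone substrate to a
chiral amine. The package re-implements, as a tested and reusable
pipeline, four analyses that such studies need:

* **Subpopulation gating** — composing a static non-zero filter, a
  pulse-width singlet filter, a GFP cut-off and an automated
  kernel-density live/dead gate on the PI channel into named
  subpopulations (Live, Live∩Single, Live∩Single∩GFP±) per timepoint.
* **Weak-acid partitioning** — the equilibrium accumulation of an
  impermeant-anion weak acid across the plasma membrane,
  `A_in/A_out = (1 + 10^(pH_in−pKa)) / (1 + 10^(pH_out−pKa))`,
  used to infer intracellular pyruvate from bioreactor supernatant
  measurements.
* **Yields and statistics** — molar product yields (mol MPPA per mol
  benzylacetone supplied), fold changes, specific yields, a
  benzylacetone mass balance, and a comparison protocol (exact
  Mann–Whitney U, Welch's t, and a normality/variance-gated one-sided
  t-test).
* **Synthetic data** — log-normal event mixtures with instrument-side
  acquisition emulation (FSC-H trigger 80 000, 10 000-event cap) and
  phenomenological diauxic fermentation time courses for the three
  growth-profile groups (I: wild-type diauxie, no product; II: no
  ethanol growth, persistent pyruvate, no product; III: producers with
  product onset at the diauxic shift), all with ground-truth labels.

It is aimed at bioprocess/microbial-engineering groups who have
per-event cytometry tables (CSV, or minimal list-mode FCS) and
fermentation time series, and want reproducible, scriptable gating and
yield accounting rather than interactive gating sessions.

## Worked example

The bundled demo pipeline simulates all three phenotype groups,
gates a simulated cytometry time series, and runs the yield,
partitioning and statistics stages:

```
cytoferm run --config configs/demo.yaml
# or: python analysis/05_pipeline.py
```

Key lines of the printed summary (seed 7, as configured):

```
"partitioning": {
  "accumulation_ratio_starved": 9.972,
  "accumulation_ratio_growth": 99.688,
  "persistent_pyruvate_flag": {"I": false, "II": true, "III": false}
},
"yields": {
  "mean_molar_yield": {"1x": 0.2227, "6x_alt1d": 0.4031, "7x_alt1d": 0.5899},
  "fold_change_vs_first_variant": {"1x": 1.0, "6x_alt1d": 1.8, "7x_alt1d": 2.6},
  "group_mppa_yield": {"I": 0.0, "II": 0.0, "III": 0.587}
},
"stats": [{"comparison": "glycerol_specific_yield_II_vs_rest",
           "method": "mann-whitney-exact", "p_value": 0.00404, ...}]
```

Reading: with pyruvate's pKa of 2.5 and the bioreactor held at pH 5, a
cell at intracellular pH 6 (glucose-starved) accumulates pyruvate
~10-fold and at pH 7 (glucose growth) ~100-fold, so the ~0.17 g/L
measured outside a non-growing group II culture implies tens of mM
inside — enough to product-inhibit the transaminase. The simulated
producer variants yield 0.22, 0.40 and 0.59 mol/mol, i.e. 1.8- and
2.6-fold increases over the single-copy strain, and only group II
cultures keep their post-shift pyruvate in the 0.13–0.20 g/L
persistence band (flagged above). The group II glycerol-yield elevation
is detected by the exact Mann–Whitney test at p = 0.004.

The numbered scripts under `analysis/` run the same stages separately
(01 simulate, 02 gating recovery, 03 partitioning, 04 yields + stats,
05 full pipeline) and write their tables under `results/analysis/`;
bulky per-event tables go to `scratch/`. Command-line subcommands
(`simulate-events`, `simulate-course`, `gate`, `partition`, `yield`,
`stats`, `run`) expose each stage; see `cytoferm --help`.

Every output CSV carries a `# config_hash: …` comment line tying it to
the configuration that produced it (read back with `comment="#"`), and
all randomness flows from the single configured seed, so reruns are
byte-identical.

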