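# necrosip

Analysis toolkit for H₂¹⁸O DNA stable-isotope-probing (SIP) experiments on
the decomposition of **microbial necromass** (dead microbial biomass) in
soil.

## The problem

A large share of soil organic carbon derives from dead microbial cells, and
how fast the necromass of *individual* taxa decomposes is hard to observe:
in bulk soil, DNA from dead and living cells is mixed. One experimental
solution is to sterilize soil (turning its whole community into necromass),
re-inoculate it with a small amount of live soil, and incubate with heavy
water (H₂¹⁸O). Actively growing decomposers synthesize ¹⁸O-labeled, denser
DNA, so after CsCl density-gradient ultracentrifugation the **light**
fractions (1.710–1.747 g ml⁻¹) contain necromass DNA and the **heavy**
fractions (1.753–1.790 g ml⁻¹) contain DNA of active microbes.

Tracking per-taxon necromass then combines qPCR and amplicon sequencing of
the light fraction. For OTU *o* at timepoint *Tᵢ*, with *F* the total 16S
copies by qPCR and *P* the OTU's sequencing proportion, the absolute
abundance is *A = F·P* and the decomposition percentage is

```
D = (A_T0 − A_Ti) / A_T0 × 100%  =  (F_T0·P_T0 − F_Ti·P_Ti) / (F_T0·P_T0) × 100%
```

Only OTUs above 0.05% mean relative abundance at day 0 (strictly) enter the
analysis, and only OTUs with mean D > 0 enter downstream comparisons.
Per-OTU significance is a two-sided t-test of replicate abundances at day 0
vs day Tᵢ (n = 4 destructive replicates, α = 0.05); group contrasts compare
gram-positive (Actinobacteria, Firmicutes) vs gram-negative (Acidobacteria,
Gemmatimonadetes, Proteobacteria) phyla, and Pearson correlations relate D
to community-inferred traits (genomic GC content, genome size).

Because per-fraction, qPCR and OTU tables from real experiments of this
design are rarely deposited in reusable form, the package ships a
first-class **synthetic experiment generator** that simulates the whole
measurement chain — first-order per-taxon necromass decay, regrowth of the
inoculated decomposers, Gaussian banding on the density gradient, lognormal
qPCR error, multinomial sequencing counts — with known ground truth, so
every pipeline stage has a parameter-recovery test surface.

## What is in the package

| module                 | contents |
| ---------------------- | -------- |
| `necrosip.simulate`    | community generator (taxonomy, GC, genome size, decay/growth rates), timecourse kinetics, qPCR + sequencing measurement model, ground-truth D |
| `necrosip.gradient`    | buoyant density model ρ = 1.660 + 0.098·GC + 0.042·a, gradient fractionation, light/heavy pooling, peak-shift and sterility QC |
| `necrosip.decompose`   | absolute abundance A = F·P, day-0 prevalence filter, decomposition statistic D, Welch/Student t-tests with BH q-values, gram-group and per-phylum summaries |
| `necrosip.traits`      | best-hit genome assignment by local alignment (or drop-in blast-tabular hits), db-weighted tie averaging, abundance-weighted OTU trait estimates, trait–D Pearson correlations |
| `necrosip.pipeline` / `necrosip.cli` | config-driven end-to-end runs with a machine-readable report; `necrosip` CLI with `simulate`, `pool`, `decompose`, `traits`, `correlate`, `run`, `report` subcommands |

## Worked example

```sh
necrosip run --seed 1 --outdir demo
```

runs the default synthetic experiment (200 taxa, days 0/15/30, 4
replicates, 50 000 reads/sample, 5% qPCR CV) through the full pipeline and
prints:

```
INFO necrosip: simulating community: 200 taxa, timepoints (0, 15, 30), 4 replicates
INFO necrosip: gradient QC: peak shift 0.0367 g/ml, sterility pass=True
INFO necrosip: day-0 prevalence filter: 151 of 200 OTUs retained
INFO necrosip: day 15: 151 retained OTUs, 134 significant
INFO necrosip: day 30: 151 retained OTUs, 143 significant
{"day15": 52.7506964770771, "day30": 70.12600096100759}
report written to demo/report.json
```

Reading the output: the heavy/light DNA peaks are separated by 0.0367
g ml⁻¹ on the discrete 24-fraction grid (the labeled community bands ~0.038
g ml⁻¹ above the unlabeled one at the default 0.9 atom fraction); an
uninoculated tube shows no heavy DNA (sterility check passes); 151 of 200
OTUs exceed the 0.05% day-0 abundance cutoff; and by day 30, 143 of them
(94.7%) have significantly lower absolute abundance than at day 0. The
final line is the community-wide necromass decline: 52.8% by day 15 and
70.1% by day 30 — fast early decay, slower afterwards, emerging from decay-
rate heterogeneity across taxa. `demo/` also contains the OTU, qPCR,
fraction, decomposition, gram-comparison, phylum-summary and
trait-correlation tables plus `report.json` with the resolved config and
its hash; re-running with the same seed reproduces every file byte for
byte.

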