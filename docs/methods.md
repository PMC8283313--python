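# Methods

This note documents the models behind `necrosip`, the defaults and why they
were chosen, and what the synthetic-data tests do and do not demonstrate.

## Experimental design being modeled

Sterilized soil is re-inoculated with 1% live soil and incubated with
H₂¹⁸O; destructive samples are taken at days 0, 15 and 30 with four
replicates. DNA from each sample is separated on a CsCl gradient into ~24
fractions; fractions at 1.710–1.747 g ml⁻¹ are pooled as the *light*
(necromass) fraction and 1.753–1.790 g ml⁻¹ as the *heavy* (active)
fraction. Per-OTU absolute abundance in the light fraction is A = F·P
(qPCR total × sequencing proportion), and decomposition is the percentage
loss of A relative to day 0.

## Synthetic experiment generator

### Community

Taxa are drawn over eight common soil phyla (Actinobacteria,
Proteobacteria, Acidobacteria, Gemmatimonadetes, Firmicutes,
Planctomycetes, Bacteroidetes, Thaumarchaeota) with genus templates typical
of agricultural soils. Gram status is proxied by phylum exactly as in the
group comparison (positive: Actinobacteria + Firmicutes; negative:
Acidobacteria + Gemmatimonadetes + Proteobacteria; others
`not_applicable`). Traits: GC ~ truncated Normal(0.66, 0.04) on
[0.58, 0.75]; log₁₀ genome size ~ Normal(6.6, 0.25). The GC range is
deliberately on the high, narrow side of the soil spectrum so that, with
the default labeling level, necromass bands fall inside the light window
and labeled bands inside the heavy window (see *Gradient model*); pushing
GC below ~0.55 would place unlabeled bands below 1.710 g ml⁻¹, which the
pooling windows cannot represent. Day-0 necromass abundances are lognormal
(σ = 1.5) normalized to 10⁹ 16S copies g⁻¹, giving ~75% of taxa above the
0.05% day-0 cutoff at n = 200.

### Decay-rate link

Per-taxon decay rates follow a softplus link on *standardized* traits:

```
k_i = softplus(β₀ + β_gc·z(gc_i) + β_size·z(log10 size_i) + ε_i),  ε_i ~ N(0, σ_k)
```

with z(·) using the generator's own population moments (exact
truncated-normal mean/SD for GC). Standardization was chosen over raw
trait values because the raw GC spread (SD ≈ 0.035) makes any
per-unit-GC coefficient numerically extreme; on the z-scale the two betas
are unit-comparable and a coefficient of 0.5 induces a k–GC Pearson
correlation of ≈ 0.4 at the defaults. Defaults β₀ = −3.0, σ_k = 0.9 give a
median k ≈ 0.05 d⁻¹ and an abundance-weighted community decline of ≈ 52%
by day 15 and ≈ 70% by day 30 — the fast-then-slow pattern arises purely
from rate heterogeneity, with fast taxa exhausted early. A two-phase decay
(fast fraction 0.6, slow-rate factor 0.1) is available behind
`two_phase=True`. `k_fixed` overrides the link with one rate for all taxa,
which is how null (type-I) experiments are built: "no decomposition
differences" for the abundance t-test means k = 0.

### Kinetics and noise

- necromass_i(t) = N₀ᵢ·exp(−kᵢt) (or the two-phase mixture);
- active_i(t) = 0.01·N₀ᵢ·exp(gᵢt) capped at 1.1·N₀ᵢ, gᵢ ~ U(0.20, 0.35) d⁻¹.
  The cap and growth range were set so total 16S rises tens of percent over
  the incubation while the light-fraction share of recovered DNA falls to
  roughly one third by day 30, the regime such experiments report;
- replicate noise: mean-preserving lognormal, CV 0.15, on necromass at all
  timepoints (destructive replicates are independent soils) and on active
  pools at t > 0 (at day 0 the active pool is exactly the inoculum);
- qPCR: F is mean-preserving lognormal around the true pool sum, CV 0.05
  (multiplicative error is the standard qPCR error model);
- sequencing: multinomial with 50 000 reads per sample; light samples draw
  from necromass pools, heavy samples from active pools. PCR bias,
  chimeras and read-level errors are *not* modeled — the pipeline starts at
  OTU counts.

All stages derive independent RNG substreams from one seed
(`SeedSequence(seed, spawn_key=(stage,))`), so outputs are bit-identical
given a config.

## Gradient model

Buoyant density is linear in GC and in the ¹⁸O atom fraction excess *a*:
ρ = 1.660 + 0.098·GC + 0.042·a g ml⁻¹. The intercept and GC slope are the
classical CsCl values for native DNA; 0.042 g ml⁻¹ is the full-labeling
shift used in quantitative-SIP work. All three are configurable. Each
taxon-pool forms a Gaussian band (SD 0.002 g ml⁻¹ by default) integrated
over 24 equal-width bins spanning 1.690–1.800 g ml⁻¹; band mass is
renormalized to the covered range so DNA is conserved to machine precision,
and bands not covered to ±4 SD raise a warning flag. Real tubes are not
exactly linear in density; no tube geometry is modeled.

Pooling windows are inclusive on both edges; the 1.747–1.753 gap maps to
`unassigned`. Peak locations are read off the discrete fraction grid
(argmax of DNA amount, ties to the lightest fraction), matching how a
fraction-vs-density curve is read; a continuous mode refines the Gaussian
mixture's mode to numerical precision (bounded scalar minimization seeded
at the best band center) and is used for the noise-free physics tests,
where the fully-labeled vs unlabeled peak shift equals 0.042 and the
0.9-atom-fraction shift equals 0.0378 g ml⁻¹ exactly as band SD → 0. At
the defaults ≥ 99% of necromass DNA pools light and ≥ 95% of active DNA
pools heavy, which is asserted in the tests.

The light-fraction "recovery" proportion is reported over all fractions of
the tube; whether the experimental quantity is per-tube recovered DNA or
something else is ambiguous in practice, and this reading is the one the
QC report implements.

## Decomposition statistics

- **Anchor**: A_T0 is the day-0 replicate-mean absolute abundance of the
  light fraction in the labeled treatment. Per-replicate D at Tᵢ is taken
  against that mean — destructive sampling provides no replicate pairing,
  and this choice preserves replicate spread at Tᵢ without inventing
  pairs. The restriction to light/labeled samples can be switched off
  (`restrict=False`) to anchor on any sample set.
- **Filters**: day-0 mean proportion strictly > 0.05% (the boundary is
  excluded); positive filter D_mean > 0 applied to the replicate mean, not
  per-replicate values. OTUs with zero counts in all Tᵢ replicates get
  D = 100 and are tested as usual.
- **Significance**: two-sided two-sample t-test of per-replicate A at T0 vs
  Tᵢ; Welch by default (a `student` option exists) since nothing
  guarantees equal variances. Degenerate inputs follow fixed conventions:
  both groups constant and equal → p = 1; constant and different → p = 0;
  fewer than 2 replicates → missing. Raw p < α defines the
  per-OTU flags; Benjamini–Hochberg q-values are reported alongside but do
  not drive the flags, keeping the flag semantics of a per-feature t-test
  at n = 4.
- The gram-group contrast is a two-sided t-test across OTU-level D means,
  restricted to the five gram-proxied phyla.

Welch at n = 4 on lognormal-ish abundances is mildly conservative: null
simulations reject at ~3–5% at α = 0.05. This is a property of the test at
this sample size, not a calibration knob.

## Trait inference

The default scorer is affine local alignment (match +2, mismatch −3, gap
open −5, extend −2 — a bit-score-like contract); an exhaustive
Smith–Waterman oracle in the test suite pins down every score. Ties at the
maximum are averaged weighted by the genomes' relative abundance in the
database (`db`), with a `uniform` option; "relative abundance" is read as
database frequency, not amplicon abundance — both weightings exist because
the phrase is genuinely ambiguous in the field. Per-OTU estimates are
means over member sequences weighted by member read abundance, so
estimates are convex combinations of database values. Precomputed
12-column blast-tabular hits can replace the built-in scorer. Genome size
is correlated with D on the raw base-pair scale by default (log₁₀ option
available). The packaged ~20-genome database is synthetic (markers mutated
from a common ancestor); it exercises the machinery but says nothing about
real reference databases.

## Pipeline and problem sizes

One YAML config drives every stage; unknown keys are rejected by name and
the resolved config plus SHA-256 hash is embedded in `report.json`.
Timepoints are integer days in explicit metadata columns; sample ids are
never parsed. Missing values are written as empty fields.

Problem sizes used by the test suite and acceptance script — 200 taxa for
recovery and direction-recovery runs, 400 OTUs for the per-OTU null, 400
small (30-taxon) simulations for the gram-group null, 100 runs for
direction recovery in the tests and 50 in the script — were chosen as the
smallest sizes at which the binomial/correlation tolerances quoted in the
tests are informative.

## Known limitations

- Single-exponential (optionally two-phase) decay; no interactions between
  taxa, no re-assimilation of necromass carbon into new biomass pools.
- The inoculum's own dead cells (≤ ~1% of necromass) are not tracked
  separately; the inoculum size is a parameter, not a fate model.
- No 16S copy-number-per-genome correction — all quantities stay in 16S
  copy units.
- No compositional transformations: the method is F·P by construction.
- Fungal communities and raw-read processing are out of scope.
- Passing parameter-recovery tests on synthetic data shows the estimator
  chain is consistent under the stated noise model; it does not validate
  the noise model itself against any particular real experiment.
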