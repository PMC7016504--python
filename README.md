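# svpools

Quantitative analysis of **functionally recycled synaptic-vesicle pools** in
annotated 2D electron-micrograph cross-sections of presynaptic terminals.

In FM-dye photoconversion experiments, vesicles that recycled during evoked
activity become electron-dense (PC+, *recycled*) while the remainder stay
clear (PC−, *resting*). Given per-synapse annotations — vesicle centers in
nm, a recycled/resting label per vesicle, and a polyline trace of the active
zone (AZ) — `svpools` computes, per synapse and per experimental group
(control, LTP, forskolin):

- **Recycled pool fraction** `f = N_PC+ / N_total`, with the standard
  inclusion filters (fraction > 0.049, ≤ 100 vesicles per section, single
  AZ), group summaries (mean ± SEM, sample SD), ordered 25% bins, top-25%
  subsets, a "potentiated" threshold `mean + 2·SD` of the control group, and
  Spearman size–fraction correlations including the residual correlation
  after removing the control group's size–fraction trend.
- **Spatial organization**: rigid re-orientation so the AZ is horizontal at
  the bottom, raw Euclidean distances from each vesicle center to its
  nearest point on the AZ polyline, per-pool cumulative distributions, and
  laterally folded, Gaussian-smoothed 10×10 spatial frequency density maps
  normalized to the cluster boundaries.
- **Clustering index**: for expanding concentric bins (20 nm radial steps)
  around each focal PC+ vesicle, the local PC+ fraction among neighbors
  (focal excluded), normalized by the focal-excluded whole-cluster fraction
  `(N_R − 1)/(N − 1)` so the index is exactly 1 at the enclosing radius;
  per-radius one-sample t tests against 1; peak cluster amplitude (mean
  index over 40–240 nm); compartment-restricted profiles (active zone
  0–35 nm, front 35–100 nm, middle 100–300 nm, rear/side 300–800 nm) with
  two-way ANOVA (condition × compartment), Sidak/Bonferroni post-hocs, and
  Kruskal–Wallis tests.
- **AZ-associated pool**: the first line of vesicles with access to the
  release site — membrane within 20 nm of the AZ and an unobstructed line
  of sight (no other vesicle disc strictly intersecting the sight segment).
- A **synthetic synapse generator** with known ground truth: hard-core
  vesicle packing (random sequential adsorption) inside a flattened-ellipse
  boundary, per-synapse recycled fraction drawn from a Beta law
  parameterized by (mean, SD), optional exponential AZ-proximity bias of
  labels, and optional nearest-neighbor label contagion — so every stage of
  the pipeline can be validated end to end without external data.

## Worked example

Simulate a control and an LTP-like study, analyze both, and compare:

```
$ svpools simulate --condition control --seed 1 --out control_ds
wrote 56 sections to control_ds
$ svpools simulate --condition LTP --seed 2 --out ltp_ds
wrote 72 sections to ltp_ds
$ svpools analyze control_ds --out control_an
included 46 of 56 sections; tables written to control_an
$ svpools analyze ltp_ds --out ltp_an
included 62 of 72 sections; tables written to ltp_an
$ svpools compare control_an ltp_an --out cmp
fraction means: a=0.182 b=0.282 (t=-3.33, p=0.00121); compare.json written to cmp
$ svpools report cmp --out rep
svpools comparison report
==============================
group a: n=46  fraction mean=0.182 +/- 0.017 (SEM), SD=0.116
group b: n=62  fraction mean=0.282 +/- 0.022 (SEM), SD=0.177
potentiated threshold (mean_a + 2 SD_a) = 0.415; proportion of group b above = 0.210
fraction t test: t=-3.327, p=0.001207
variance F test: F=2.314, p=0.003843
...
```

The control group draws per-synapse fractions from Beta(mean 0.16, SD 0.10)
and the LTP group from Beta(mean 0.30, SD 0.21) with an AZ-proximity label
bias (decay length 150 nm); the comparison recovers the configured contrast
— the LTP group's larger mean and variance (t and F tests), the filter
counts (10 of 56 control sections fall at or below the 0.049 fraction
bound), and the AZ-pool enrichment produced by the label bias. `analyze`
writes per-synapse tables (`fractions.csv`, `distances.csv`, `profiles.csv`,
`amplitudes.csv`, `compartments.csv`, `az_pool.csv`, density matrices) and
a manifest with the resolved configuration; `compare` writes all group
statistics to `compare.json`.

The same operations are available as a library:

```python
from svpools import (control_config, generate_group, filter_sections,
                     clustering_profile, population_cluster_test)

sections, truth = generate_group(control_config(), master_seed=1)
kept, report = filter_sections(sections)
profiles = [clustering_profile(s) for s in kept]
print(population_cluster_test(profiles, alpha=0.01).head())
```

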