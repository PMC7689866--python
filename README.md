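# calyxsf

Structure–function analysis of the developing calyx of Held synapse.

During the first postnatal week, each principal neuron of the medial
nucleus of the trapezoid body (MNTB) goes from several small glutamatergic
inputs to a single giant axosomatic terminal — the calyx of Held. `calyxsf`
is a pipeline for the analysis that links the two sides of this transition:

* **in vivo physiology** — detect EPSPs, postsynaptic APs and presynaptic
  prespikes in current-clamp recordings; decompose evoked responses into
  discrete synaptic inputs by their afferent-stimulation recruitment
  (Welch-t gate on latency and rate of rise, similar-latency subtraction,
  spontaneous-activity cross-check); compute per-cell strength rosters and
  the competition index;
* **3D morphology** — segment the biocytin-filled soma (sphere flood fill,
  IsoData auto-threshold) and the VGluT-positive terminal clusters
  (26-connected flood fill) in anisotropic fluorescence stacks; bridge the
  synaptic cleft with a per-cell optimized dilation; quantify per-cluster
  somatic contact areas, coverage and the contact ratio;
* **statistics** — the structure–function power law
  `RoR = β · area^α` fitted on the log–log scale, age regressions (with
  rank transforms and age correction), the logistic developmental switch of
  prespike presence, Welch tests, Bonferroni correction and conduction-speed
  estimates.

Throughout, synaptic strength is the EPSP maximal rate of rise (RoR, V/s) —
the standard strength proxy in this preparation, because strong EPSPs
trigger APs and truncate their own amplitudes.

A first-class synthetic-data module generates cohorts of cells, membrane-
potential traces (stimulation experiments and spontaneous bursts) and
two-channel voxel volumes with complete ground truth, so every stage of the
pipeline is verifiable without any recordings.

## Worked example

```python
import numpy as np
from calyxsf.sfstats import pearson_r, regression_f, powerlaw_fit, conduction_speed
from calyxsf.synth import make_cohort, structure_function_records
from calyxsf.datatypes import CohortParams

# Four cells with measurable prespikes: peak-to-peak amplitude (mV)
# against the contact area of the largest VGluT cluster (um^2)
amps  = [0.11, 0.26, 0.30, 0.37]
areas = [19.2, 23.1, 25.6, 59.7]
r = pearson_r(amps, areas)
res = regression_f(np.array(amps), np.array(areas))
print(f"prespike amplitude vs largest-cluster area: "
      f"r = {r:.2f}, F(1,{res.df[1]}) = {res.F:.1f}, p = {res.p:.2f}")

# structure-function power law on a synthetic 20-cell cohort
cells = make_cohort(CohortParams(n_cells=20, seed=42))
a, rr = structure_function_records(cells)
fit = powerlaw_fit(a, rr)
print(f"power law: beta = {fit.beta:.1f} +- {fit.se_beta:.1f} V/s/um^2a, "
      f"alpha = {fit.alpha:.2f} +- {fit.se_alpha:.2f}, r_log = {fit.r_log:.2f}")

print(f"conduction speed at 2.1 ms latency: {conduction_speed(2.1):.1f} m/s")
```

prints

```
prespike amplitude vs largest-cluster area: r = 0.76, F(1,2) = 2.8, p = 0.24
power law: beta = 5.4 +- 0.9 V/s/um^2a, alpha = 0.43 +- 0.06, r_log = 0.87
conduction speed at 2.1 ms latency: 0.6 m/s
```

The prespike correlation rounds to r = 0.8 with F(1,2) = 3: a strong but —
with four cells — non-significant association between the presynaptic AP
signature and terminal size. The power-law fit on one 20-cell cohort
scatters around the generating values (β = 6.8, α = 0.35); averaged over
many seeds it recovers them (see the test suite). The conduction speed is
the crude axonal estimate: 1 mm of axon divided by the latency after a
0.5 ms synaptic delay.

## Command line

```bash
calyxsf full-run --out results --seed 1        # simulate -> detect -> identify -> segment -> correlate
calyxsf detect --out results_phys --seed 1     # physiology only
calyxsf make-fixtures --out fixtures --seed 0  # the 4-cell demo/fixture tree
```

Outputs: per-cell input rosters (JSON), contact reports (JSON), a cohort
TSV and a report with the power-law fit and age slopes. Exit codes:
0 success, 2 configuration error, 3 stage error. A YAML config (see
`calyxsf.pipeline.PipelineConfig`) pins every threshold; rerunning a config
is byte-identical.

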