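# Methods

`calyxsf` reimplements, as a tested pipeline, the computational chain that
links in vivo synaptic physiology of the developing calyx of Held synapse to
3D light-microscopy quantification of presynaptic contact area. This note
describes the models, the parameters that matter, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## The scientific setting

During the first postnatal week, principal neurons of the medial nucleus of
the trapezoid body (MNTB) transition from innervation by several small
glutamatergic inputs to the one-to-one innervation by a single giant
terminal, the calyx of Held. Input strength is measured in vivo as the EPSP
maximal rate of rise (RoR, V/s) — amplitudes are unusable because strong
EPSPs trigger postsynaptic APs. Structure is measured ex vivo as the somatic
contact area of VGluT-immunolabelled terminal clusters in 3D fluorescence
stacks of the recorded (biocytin-filled) cell. The package's central result
is the structure–function power law

    RoR = β · area^α ,    with defaults β = 6.8 V/s/µm^2α, α = 0.35,

fitted by OLS on the log–log scale (α = slope, β = exp(intercept), SE of β
by the delta method), together with the developmental statistics around it:
the strongest input grows ≈ 4.2 V/s per day while the second strongest stays
near 3.7 V/s; the competition index (second/strongest RoR) therefore falls
with age; prespike presence (the signature of a giant terminal) switches on
with a logistic midpoint near postnatal day 4.1 and steepness 0.7 days.

## Event detection (`calyxsf.detect`)

Traces are smoothed and differentiated with Savitzky–Golay filters
(polynomial order 3, window 0.24 ms ≈ 7 samples at 25 kHz). Events are
peaks of the smoothed dV/dt above a minimal RoR of 0.7 V/s, at least 0.6 ms
apart (closer events merge), with an additional minimum amplitude of 0.2 mV.
The onset is the last positive third-derivative maximum before the dV/dt
peak; the exact onset criterion of the lineage method is not published
numerically, so this variant is a documented package choice. Latency is
onset minus the preceding stimulus time; events with latency in (1, 8] ms
are evoked.

Robustness choices that matter in practice:

- Stimulus artefacts are blanked 0.3 ms post-stimulus in the dV/dt channel
  and slightly wider in the third-derivative channel (the smoothing kernel
  smears the artefact a few samples past the blank, and its third
  derivative dwarfs every EPSP onset).
- AP upstrokes are excluded by three combined filters (dV/dt above
  100 V/s, voltage already near threshold, post-AP exclusion window), and
  upstroke peaks are rejected *before* the minimum-separation rule so that
  a rejected upstroke cannot suppress the EPSP peak that caused it.
- The post-AP exclusion lasts 4.5 ms: repolarization and AHP-recovery
  slopes mimic slow EPSP rises.
- The RoR of an EPSP that triggers an AP is measured up to the dV/dt
  valley between the synaptic rise and the AP takeoff (pre-AP measurement);
  an EPSP so strong that it reaches threshold while its dV/dt is still
  rising is recovered from the AP takeoff with an early-window measurement.
  With the generator's AP threshold this keeps the measured RoR faithful to
  ≈ 40 V/s, mildly compressed above.
- Events riding a recovering baseline (burst envelope, AHP tail) have the
  pre-onset baseline slope subtracted.

Prespikes — the small biphasic deflections of a presynaptic calyceal AP —
are detected automatically (the lineage method used visual inspection): in
a window before each event's rising phase, the trace is detrended with the
extrapolated pre-event baseline; the deflection must exceed k·σ (default
k = 3) peak-to-peak and deflect both above and below the trend by 1.2 σ,
with σ the robust SD of the slow-trend-removed event-free trace.
Peak-to-peak amplitude is read from the raw trace (smoothing attenuates a
0.5 ms-wide wave). An input "has a prespike" when at least 50% of its large
events carry one. P_AP is the fraction of an input's EPSPs followed by an
AP within 2 ms.

## Input identification (`calyxsf.inputs`)

Evoked events are grouped by stimulation intensity. Between consecutive
intensities, Welch's t is computed for latency and for RoR; a transition is
flagged as a new input when |t_lat| + |t_RoR| > 6 AND the mean RoR rises by
more than 20%. A flagged transition whose response rate jumps by more than
20 percentage points with t_lat < 2 *and* t_RoR < 4 is reclassified as an
activation-probability shift (the t_RoR guard is a package refinement: a
pure probability change cannot move the RoR distribution). When the evoked
latency distribution is bimodal (populations near 1–3 and 4–8 ms), the scan
runs per latency domain, split at the KDE density minimum between 3 and
4 ms.

Candidate RoRs are read from per-intensity RoR modes (log-scale KDE with a
bandwidth capped at 0.25 log-units — Silverman's rule over-smooths when one
giant mode inflates the spread; events join their nearest mode). A new mode
whose latency lies within ±0.5 ms of known inputs is corrected by
subtracting their RoRs — co-active inputs closer than the 0.6 ms event
separation fuse into summed EPSPs, which is exactly what the subtraction
rule compensates. Two situations defeat the t gate and are handled by a
direct mode pass: an all-or-none giant input (the recruited/failed mixture
inflates the group variance) and a moderate input recruiting against a much
stronger background (the group mean barely moves). Any persistent RoR mode
above 2.5 V/s that no known input explains spawns a candidate.

Every candidate must be corroborated by the spontaneous activity: accepted
only if a spontaneous EPSP lies within ±20% of its RoR. Spontaneous events
whose rise was cut by an AP underestimate their input by up to ≈ 30%, so a
truncated event in [0.7, 1.2]× the candidate also corroborates it. With no
spontaneous data the candidate passes flagged "unchecked". Additional
inputs are read off the modes of the spontaneous RoR distribution
(log-scale KDE, Silverman bandwidth, prominence ≥ 10% of the peak density);
this is how a strongest input that electrical stimulation failed to recruit
is recovered. Near-duplicate candidates merge (RoR within 1.5×, latency
within 0.3 ms), estimates are refined by assigning each evoked event to its
nearest compatible candidate (±35% RoR, ±0.6 ms), and evoked + spontaneous
rosters are deduplicated at ±20% RoR with evoked provenance preferred
(±35% for strong inputs, whose spontaneous modes are biased low by burst
depolarization and truncation). Inputs above 10 V/s are "strong"; the
competition index is the ratio of the two strongest.

## Segmentation (`calyxsf.seg3d`)

Volumes are ZYX grids with physical voxel sizes (defaults 110 nm axial,
41 nm lateral — the SIM sampling). All geometric operations are defined in
physical micrometres and are therefore ellipsoidal in index space.

- **IsoData**: iterative intermeans on the raw intensity values,
  `T ← (mean(I≤T) + mean(I>T))/2` from the midrange until the partition
  stabilizes — a fixed point of the intermeans map (tested against an
  exhaustive fixed-point search and against the histogram-binned reference
  implementation).
- **Sphere flood fill**: a probe of physical radius 400 nm scans the fill
  channel; a voxel joins the cell body when ≥ 40% of the probe (clipped at
  volume borders) is above threshold (IsoData of the channel by default).
  Largest 26-connected component wins. Implemented with FFT convolutions.
- **Marker clusters**: 26-connected components of the above-threshold
  marker voxels; components under 10 voxels are discarded as specks;
  labels are dense, ordered by size.
- **Dilation**: anisotropy-aware Euclidean distance transform; the amount
  (0.16–0.76 µm, step one lateral voxel, ties to the smallest) is optimized
  per cell by maximizing the fraction of the dilated surface covered by
  marker clusters. Marker voxels buried strictly inside the dilated body no
  longer count as covering it — without this, overshooting the clusters
  costs nothing and the optimum drifts outward.

Contact areas use orientation-corrected face counting: each exposed voxel
face contributes its physical area divided by |n_x|+|n_y|+|n_z| of the
local surface normal (from a Gaussian-smoothed mask). Raw face counting
overestimates oblique surfaces by up to ~1.5×; the corrected estimator is
within ~3% of the analytic area for spheres at SIM voxel sizes (raw
counting remains available via `correct_faces=False`). Per cluster, the
contacted footprint is the coincident one (surface voxels inside the
cluster) when the surface is embedded in the cluster — unbiased at every
cap size — and otherwise the 26-adjacent footprint with boundary-rim
voxels weighted ½ (adjacency expands a footprint by about one voxel ring).
A contested surface voxel goes to the cluster with the nearest centroid, so
per-cluster areas sum exactly to the total. The contact ratio is the
largest cluster's contact over the total contacted area; coverage is total
contacted over soma surface.

## Statistics (`calyxsf.sfstats`)

OLS with per-coefficient t, overall F and two-sided p (exact fits report an
overflow-safe F and p = 0); optional midrank transform and age covariate
(the age-correction pattern). Pearson r, Spearman ρ as Pearson of midranks,
Bonferroni `min(1, m·p)`. The logistic developmental switch
`P = 1/(1+exp(−(age−m)/s))` is fitted by Newton–Raphson maximum likelihood
with delta-method SEs; quasi-separated data are flagged non-converged with
s floored at 0.1 days. Conduction speed is the crude estimate
`axon length / (latency − synaptic delay)` with 1 mm and 0.5 ms defaults.
The exact logistic midpoint of the real cohort cannot be reproduced from
grouped counts alone (grouped fits are separation-degenerate under MLE), so
the fit is validated by parameter recovery from its own published values.

## The synthetic-data generator (`calyxsf.synth`)

The generator's defaults are the study conditions: cohorts of 32 cells,
ages uniform over P2–8; input counts from a truncated normal 5.6 ± 1.6
(minimum 2); strongest input mean RoR `8 + 4.2·(age−2)` V/s with lognormal
cell-to-cell spread (σ = 0.25); second strongest lognormal around 3.7 V/s
(σ = 0.30, capped below 0.85× the strongest); remaining inputs log-uniform
in 0.7–2 V/s. Per input: recruitment threshold uniform 0.08–0.40 mA,
activation probability uniform 0.59–1.0, latency from the two observed
populations (1.2–3 ms, 4–8 ms; strong inputs always short-latency), latency
jitter CV 1.0–3.8%, per-trial RoR CV 7–38%. Prespike presence on the
strongest input follows the logistic switch (midpoint 4.1 d, steepness
0.7 d), with peak-to-peak amplitudes uniform in 0.1–0.4 mV. True contact
areas invert the power law exactly, so β·area^α = RoR to machine precision;
the *observed* structure–function RoR additionally carries lognormal
observation noise (σ = 0.36, derived analytically so the default cohort's
log–log correlation is ≈ 0.8).

Traces: difference-of-exponentials EPSP kernels (rise 0.4 ms, decay 3 ms)
whose onset is smoothed by a 0.12 ms Gaussian — the raw kernel has a
derivative discontinuity at onset, which makes "maximal dV/dt" ill-defined
under any smoothing-based measurement; the smoothed kernel's amplitude is
solved numerically on the sampled grid so its maximal dV/dt equals the
target RoR exactly. Stereotyped APs (overshoot to +10 mV, slow AHP decaying
over ~14 ms) are inserted wherever the summed depolarization crosses a
threshold of 12 mV above rest; ground-truth RoR is recorded pre-AP. The
threshold value matters: much lower values truncate strong EPSPs mid-rise
and destroy the information the detector is supposed to recover. Calyceal
inputs contribute a biphasic derivative-of-Gaussian prespike (width 0.5 ms)
centred 0.45 ms — the synaptic delay — before the EPSP onset; with shorter
leads the negative lobe is swallowed by the EPSP foot and no measurement
can recover the inserted amplitude. Stimulation experiments concatenate
40 ms sweeps (stimulus at 5 ms, brief biphasic artefact included), 30
sweeps per intensity, ascending. Spontaneous activity is a Poisson process
of bursts (default 0.2 Hz, 1 s long) within which each input fires at
10 Hz; these burst statistics are free parameters of the emulation, not
published values. Membrane noise is band-limited Gaussian (0.4 ms
correlation, 0.05 mV RMS).

Volumes: the soma is a mildly anisotropic ellipsoid; marker caps are
spherical-cap shells (thickness 0.25 µm) apposed across a 0.2 µm cleft,
placed by rejection sampling with ≥ 2-voxel gaps; cap angular extents are
solved by numerical quadrature on the cleft-offset ellipsoid so the
delivered contact area matches the requested one (caps larger than 40% of
the soma surface are clipped — a near-hemispheric terminal cannot be a
disjoint cap, and its measured contact is a lower bound in any case, as for
real calyces). Channels are blurred with a Gaussian PSF and corrupted with
Gaussian (optionally Poisson) noise. The ground-truth contact report is
measured on the noise-free label geometry with the same estimator the
analysis uses, with the reference surface embedded two voxels into the
shell so the unbiased coincident-footprint path applies.

What the generator does **not** emulate: dendrites and axonal biocytin
signal (the real analysis removed these manually; an exclusion-mask input
replaces that step), multi-cell scenes, SIM reconstruction artefacts,
conductance-based membrane dynamics, NMDA plateau potentials, and
activity-dependent plasticity. Passing recovery tests therefore show that
the analysis chain is correct and unbiased under the assumed statistical
structure — not that it would be artefact-free on arbitrary real data.

## Problem sizes and tolerances

Recovery suites run at desk scale as the package's own defaults: the
developmental recovery uses 32-cell cohorts with nine intensities × 30
sweeps (40 ms each) plus 20 s of spontaneous activity per cell, reporting
medians over cohorts (16 in the test suite, 50 in the acceptance script);
the dual-arm structure–function recovery runs 10-cell cohorts at 2× coarser
voxels over 5 seeds; contact-fidelity checks run single somata of 3–4.5 µm
radius at native SIM voxels. Somata in volume runs default to 3–4 µm radius
(real MNTB somata are ≈ 7 µm; the geometry scales, the surface estimator
does not care). Convergence/tie rules: IsoData iterates until the partition
is stable; dilation ties go to the smallest distance; equal-RoR inputs rank
by earlier latency.

## Known limitations

- Weak inputs (0.7–2 V/s) with per-trial CV up to 38% are not separable as
  distinct RoR modes; the identified input count underestimates the true
  count by 1–3 in most cells, mirroring the acknowledged undercount of
  small inputs in the in vivo analysis. The strongest and second strongest
  inputs — everything the downstream statistics use — are recovered
  reliably (strongest within 15% of truth in ≈ 90% of cells).
- Inputs whose RoR *and* latency both lie within the event-merging window
  of a stronger input are genuinely invisible; the subtraction rule
  recovers their contribution only at recruitment transitions.
- Contact areas of merely-touching clusters carry the half-rim adjacency
  bias (a few % for ≥ 2 µm², up to ~20% at 0.4 µm²); the optimized dilation
  normally embeds the surface and avoids this path.
- The measured RoR compresses above ≈ 40 V/s when EPSPs reach AP threshold
  mid-rise; at the cohort's age range this affects only tail trials.
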