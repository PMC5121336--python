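# Methods

`ldlscreen` implements the quantitative pipeline of a genome-wide RNAi
screen for LDL uptake in endothelial cells and its follow-up assays:
plate-based hit calling, an siRNA deconvolution filter cascade, TIRF-based
detection of LDL-transcytosis (vesicle fusion) events, colocalization
statistics, and ligand-binding model fits (cell-surface saturation binding
and single-cycle SPR kinetics). Raw plates and movies for such screens are
rarely deposited, so the package ships generators that produce inputs with
the same statistical structure and planted ground truth; every claim a green
test makes is therefore a claim about recovery of planted structure, not
about any particular biological dataset.

## Screen statistics (`ldlscreen.screen`)

Each 384-well plate is normalised independently with the robust z-score

    z = (x − median) / (1.4826 · MAD),

computed over the plate's *sample* wells only. Control wells (non-targeting
siRNA negative, DNM2 siRNA positive — dynamin-2 knockdown blocks
clathrin-mediated LDL uptake and serves as the full-effect anchor) are
reserved for plate quality control via the Z′ factor

    Z′ = 1 − 3(σ_pos + σ_neg) / |μ_pos − μ_neg|,

with sample standard deviations; plates are accepted only when Z′ > 0.2
(strict). Wells need ≥ 100 cells and ≤ 20% dead cells (both boundaries
read literally: 100 cells passes, death strictly over 20% fails).
A plate whose sample MAD is zero while intensities vary raises an error
rather than silently substituting the standard deviation — silent fallbacks
mask plate failures.

Replicates (three independent screens) combine by the median of per-replicate
z; hits are called two-sided at |z| ≥ 2.5 with direction labels
(`decrease` is the tail used downstream). The aggregation (`median`/`mean`)
and the calling mode (`aggregate` vs `any`-replicate exceedance) are
configurable because neither is uniquely determined by how screens of this
design are usually described; the defaults are the robust choices.
Genes with zero surviving replicate scores are flagged unscorable, never hits.

Percent effect for follow-up assays is anchored at the controls:
0% at the negative-control mean, 100% at the DNM2 mean.

## Filter cascade (`ldlscreen.filters`)

Four rules applied per candidate gene to its four individual siRNAs, each
measured in duplicate (sets 1 and 2), as percent inhibition:

1. **DiI-LDL confirmation** — an siRNA is active iff inhibition ≥ 50% in
   *both* sets; a gene is confirmed iff ≥ 2 siRNAs are active.
2. **Transferrin specificity** — clean iff ≥ 2 siRNAs show < 30% (strict)
   Tf-FITC inhibition in both sets. By default at least one clean siRNA must
   also be DiI-active (`min_overlap=1`); whether the clean and active sets
   must overlap is genuinely open, so it is configurable, and the
   requirement is vacuous for genes with no active siRNA.
3. **LDLR independence** — per siRNA, the ratio of effect under high- vs
   low-LDLR expression; the gene is excluded as LDLR-dependent iff ≥ 2
   siRNAs show a ≥ 2-fold difference in either direction (ratio ≥ 2 or
   ≤ 0.5; a zero denominator counts as ≥ 2-fold and is logged).
4. **HUVEC re-confirmation** — rule 1 applied to the primary-cell assay.

The default stage order is DiI → Tf → LDLR → HUVEC; the order is
configurable since the verdict booleans are computed per gene regardless of
order, only the intermediate stage counts depend on it. Missing duplicates
make an siRNA inactive (logged); a gene missing a whole assay fails that
stage.

## TIRF fusion detection (`ldlscreen.tirf`)

The movie model: 150 frames at 6.67 frames s⁻¹ of the basal ~110 nm of the
cell. The pipeline is detect → link → classify:

- **Spot detection.** Pixels above `background + k_sigma·σ` (robust
  median/MAD estimates per frame, so detection is invariant to constant
  offsets) are segmented; blobs pass if area ∈ [3, 150] px, circularity
  `4π·area/perimeter² ≥ 0.5` and peak above the gate. The perimeter uses
  the Crofton estimate — the naive pixel-boundary perimeter collapses for
  1-px-thick objects and would let lines masquerade as circular. Centroids
  are intensity-weighted (sub-pixel).
- **Linking.** Greedy nearest-neighbour frame-to-frame assignment
  (ascending distance), link threshold 5 px, gap closing up to 2 missed
  frames. Deliberately simple; see limitations.
- **Fusion classification.** For each track the per-frame intensity
  difference series `d_t = I_t − I_{t−1}` is taken over the *whole* track
  (intensity is the background-subtracted sum in a 7×7 window at the track
  position, extended 3 frames past the last detection so the collapse of a
  vanishing vesicle is still recorded at the docking site). A fusion occurs
  at the earliest t where `d_t` and `d_{t+1}` both fall below
  `mean(d) − 2.5·sd(d)` *and* the net displacement over the trailing 5
  frames is ≤ 3 px (docked). Minimum track length 10 frames (a stable
  sd(d) needs history); when sd(d) is degenerate a floor of 3× the
  camera-noise σ applies (logged), so affine decay of any slope never
  triggers.

Numerical caveat, documented deliberately: because mean and sd are plain
(not robust) statistics of d, a *smooth* exponential decay steeper than
roughly 0.03 frame⁻¹ can put its first two differences beyond 2.5 sd and
fire the detector. Realistic photobleaching (the generator default is
0.005 frame⁻¹, ~50% loss over a movie) sits far below this; the
affine-decay guarantee is exact for every slope.

Pearson correlation over masked pixels and Manders coefficients
(M1 = fraction of channel-a intensity where b exceeds its threshold; M2
symmetric) cover the confocal colocalization analyses. Zero-variance or
all-zero channels raise errors rather than returning NaN.

## Binding models (`ldlscreen.binding`)

**Saturation binding.** `B(L) = B_max·L/(K_d + L)` (+ optional linear
nonspecific term) fit by Levenberg–Marquardt with positivity bounds;
asymptotic standard errors from the covariance. Points are equally weighted
by default; per-point sigmas can be supplied for count-derived (¹²⁵I c.p.m.)
data. K_d pinned at a bound raises a fit error with the value in the
message.

**1:1 SPR kinetics.** `dR/dt = k_a·C(t)(R_max − R) − k_d·R` with C(t)
piecewise constant from the injection schedule. Because C is constant per
phase, the exact propagator `R(t) = R_eq + (R_0 − R_eq)·e^{−(k_aC+k_d)Δt}`
is used for both simulation and fitting — exact and unconditionally stable,
so no ODE stepper is needed (a `solve_ivp` run serves as an independent
cross-check in the tests). Single-cycle mode (increasing concentrations,
no regeneration) simply carries R across phase boundaries. Fitting is a
global least-squares over (log k_a, log k_d, R_max) across all phases
jointly; the log parameterisation makes the optimiser scale-free across
K_d from nM to tens of µM. Mass-transport limitation is not modelled.
Units are symbolic: K_d is reported in the schedule's concentration unit
and never converted (no molar mass is assumed for LDL particles).

Double referencing subtracts reference-surface and buffer-blank traces on a
shared time base. Competition analysis compares naive vs pre-saturated
surface fits and calls "non-competitive" when both the K_d ratio and the
amplitude ratio lie within a 2-fold band. Stability-point quantitation
reads each trace 5 s after its final injection stops (the schedule states
only "early dissociation"; 5 s clears bulk refractive-index jumps at
typical 1 Hz–10 Hz sampling) and normalises by a designated trace.

## Synthetic data (`ldlscreen.simulate`)

All generators are pure functions of (spec, seed) and emit machine-readable
ground truth.

- **Screen**: 2,000 genes × 384-well plates × 3 replicates by default — a
  desk-scale stand-in for the 18,119-gene screen. Null intensities are
  log-normal (σ_log = 0.10; fluorescence is positive and right-skewed);
  effects act multiplicatively, stated in plate-MAD units (an effect of m
  MADs multiplies the null median by 1 + m·σ_log to first order). Controls
  have 5% CV; the positive control realises an 80% uptake reduction, giving
  Z′ ≈ 0.75–0.85, comfortably above the 0.2 gate. ~1% of wells fail the
  cell-count QC.
- **Follow-up**: per-gene composition classes — true hits pass every rule
  with wide margins (DiI 60–90%, Tf 2–18%, LDLR ratio ≈ 1); each decoy
  class violates exactly one rule (single active siRNA; Tf 45–70%; 3-fold
  LDLR ratio on two siRNAs; HUVEC ≤ 30%). Replicate noise 3 percentage
  points, small against every margin, so verdicts are deterministic per
  seed.
- **TIRF**: 256×256 px field, 45 vesicles, 30 fusions by default. Vesicles
  are Gaussian PSF spots (σ = 1.4 px, peak ≈ 900 over a 100-offset
  background, noise σ = 8) doing Brownian motion (0.8 px/frame mobile,
  0.05 px/frame docked); fusing vesicles wander 3–10 frames, dock 12–25
  frames, then collapse linearly over two frames (full → half → background)
  — two equal consecutive intensity drops, the signature the two-frame
  criterion describes. Initial positions are dart-thrown with ≥ 12 px
  separation: spots closer than ~2 PSF widths are unresolvable by any
  diffraction-limited detector, and the assay counts distinct membrane
  fusion sites. Photobleaching 0.005 frame⁻¹. Not emulated: optical
  aberrations, EMCCD gain statistics, axial (TIRF-depth) intensity
  modulation during docking, cell boundaries. A green recovery test
  therefore establishes that the detector recovers well-separated planted
  events under realistic noise — not performance on crowded or drifting
  real movies.
- **Binding**: forwards through the model equations above; `two_site` sums
  two independent 1:1 species (the non-competitive scenario).

## Known limitations

- The greedy linker can swap identities when a mobile vesicle passes within
  the link radius of a docked one; no motion model or global assignment
  (e.g. Hungarian/LAP) is used.
- The fusion statistic uses non-robust mean/sd of the difference series, so
  a single track containing two collapse events (merged vesicles) inflates
  sd and can mask the smaller event.
- Kinetic fits assume the 1:1 model that generated the data; heterogeneous
  ligand and two-state models are out of scope, as is Biacore file parsing.
- The screen module starts from well-level intensities; image segmentation
  and spatial plate corrections (B-score polish) are out of scope.
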