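# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `atrialep`.  It is written for a reader who wants to know
exactly what each number produced by the package means and what the test
suite does and does not demonstrate.

## 1. Synthetic data (`atrialep.synth`)

All downstream stages are validated against generated inputs whose ground
truth is known analytically.  The generators are deterministic for a fixed
seed and return their ground truth alongside the signals.

**12-lead ECG.**  Beats are placed on a strictly periodic R-peak train at
the configured heart rate (sampling 1 kHz by default).  Each beat is a sum
of template waves: a Gaussian P wave, a Gaussian R wave (sigma 12 ms) with
a smaller S deflection, and a broad T wave.  Per-lead P amplitudes default
to typical sinus values (0.03–0.12 mV); `biphasic_v1` morphology replaces
the V1 P wave with two opposite-signed Gaussian lobes, giving a
controllable non-zero P-terminal force.  Optional corruptions: white noise,
a mains sinusoid (50/60 Hz), and a linear baseline drift.  More realistic
noise taxonomies (electrode motion, muscle artifact) are out of scope.

*Duration convention.*  A Gaussian pulse has no finite support, so "P-wave
duration" needs an operational definition.  We tie the Gaussian width to
the requested duration through the 5%-of-peak crossing
(`sigma = d / (2*sqrt(2 ln 20))`), the same rule the delineator uses.  The
annotated onset/offset therefore coincide with what an ideal delineator
should recover, and parameter-recovery errors measure pipeline error, not
a definitional mismatch.

*PR convention.*  The generator's QRS onset is defined as R − 50 ms, which
is also the end of the analysis window that the feature extractor uses as
its QRS-onset proxy, so the annotated PR interval is recoverable without a
QRS delineator.

**Activation wavefronts.**  Electrodes are placed by dart-throwing
(blue-noise) sampling on the mesh at a requested areal density, mimicking
the irregular coverage of basket/multi-spline catheters.  Three wave
geometries are supported: planar (LAT affine in the propagation
coordinate), radial from a focus, and a two-wave head-on collision whose
fronts meet mid-domain.  True CV vectors are analytic.  The unipolar
electrogram is the derivative of a Gaussian centred at the local
activation time (width parameter `egm_width/4`, default 2.5 ms), an R/S
biphasic deflection whose *maximum negative slope is exactly at the LAT* —
so the steepest-negative-slope detector has a well-defined truth.  A
separate channel carries the coronary-sinus reference deflection, and the
ground truth includes the wave's arrival time at the far end of the
domain, used as the distal-CS proxy when computing total activation time.

**Cohorts.**  Two seeded Gaussian samples with requested (n, mean, SD);
used for power/calibration studies of the statistics layer.

## 2. P-wave analysis (`atrialep.pwave`)

Preprocessing: 2nd-order IIR notch at the configured mains frequency, then
a 5th-order Chebyshev-I low-pass (100 Hz cutoff, 0.5 dB ripple).  All
filtering is forward-backward, so fiducial timing is unbiased.  Recordings
are split into consecutive 15-s epochs (trailing remainder discarded).

R peaks: Pan–Tompkins-style detector (5–15 Hz band-pass, derivative,
squaring, 150-ms integration, 200-ms refractory period, refinement to the
band-passed extremum).  For every R peak a 300-ms window starting 350 ms
before the peak is extracted per lead.

Template: per lead, each window is scored by its mean best-lag normalized
cross-correlation (lag search ±50 ms) with all others; the best-scoring
window becomes the candidate template, windows correlating < 0.9 with it
are discarded, and the survivors are aligned at their best lag and
averaged.  The template lives in the candidate's time frame; averaging at
the best lag preserves pulse amplitude (tested against the 1/sqrt(N) noise
floor).

Delineation: per lead, the template is lightly smoothed (Savitzky–Golay,
order 2, 21-ms span); baseline = median of the first 40 ms of the window;
onset/offset = start/end of the first/last *run* of at least 10 ms whose
absolute deviation from baseline exceeds 5% of the lead's peak deviation.
The run requirement (debouncing) is essential at realistic noise levels:
the 5% threshold of a small-amplitude lead sits only ~3 standard
deviations above the residual template noise, so isolated noise
excursions would otherwise set the fiducials.  Three lead-level QC rules
protect the global extremes: flat leads are excluded; leads whose
threshold falls below 3x the baseline-segment noise SD are excluded
(unless that empties the set); and leads whose delineated interval strays
more than 40 ms beyond the cross-lead median interval (well beyond
physiological inter-lead P dispersion) are treated as template artifacts
and dropped.  The global onset (offset) is the earliest (latest)
surviving per-lead value.  The 5% threshold, the baseline window and the
QC constants are declared substitutes for an unspecified clinical
delineation rule; all are configurable.

Features (5 global + 5 × 12 local = 65):

* duration = global offset − onset; PR = QRS-onset proxy (window end,
  i.e. R − 50 ms) − global onset;
* PTFV1 = trapezoidal area of the terminal negative deflection of the
  delineated V1 P wave (0 if the wave ends above baseline; reported absent
  when V1 is missing);
* FWHM = total time the dominant lead's baseline-corrected P wave exceeds
  half its peak (exactly base/2 for a triangular wave);
* P axis = atan2(net area aVF, net area I) in degrees;
* per lead: trapezoidal area, peak count (prominence ≥ 10% of lead peak),
  max |amplitude|, Shannon entropy of the 10-bin amplitude histogram
  (nats; scale-invariant by construction, 0 for a constant segment), and
  sample entropy (m = 2, r = 0.2 SD, Chebyshev distance, self-matches
  excluded — validated against a brute-force pairwise count).

Patient-level values are NaN-skipping means over epochs, with per-feature
epoch counts reported.  Means rather than medians: with ≤ 20 epochs per
recording and approximately symmetric epoch-level errors the mean is the
lower-variance choice.

## 3. Electrogram analysis (`atrialep.egm`)

Conditioning subtracts a Savitzky–Golay trend (order 2, span 201 samples)
— i.e. the filter output is used as the *trend estimate*, not the signal —
then applies a zero-phase 5th-order Butterworth band-pass, default
2–100 Hz at the 953.6 Hz clinical sampling rate.  The band was chosen to
remove residual drift while leaving a 10-ms biphasic deflection's steepest
slope in place to within one sample (tested).

LAT = time of the minimum central-difference derivative, refined to
sub-sample precision by a parabolic fit through the three samples around
the minimum (halves the ~1.05 ms quantization), minus the CS reference
time.  Detections whose derivative minimum sits at the window edge, or
whose trough is indistinguishable from the bulk derivative distribution
(depth ≤ 5 MAD), are flagged low-confidence.

Mapping: nearest-vertex projection (electrodes > 5 mm from the mesh are
dropped and counted), averaging of co-assigned LATs, then a 2-mm
neighbourhood outlier check: a vertex with ≥ 2 populated neighbours within
2 mm (Euclidean ≈ geodesic at that radius) is excluded when its LAT
deviates > 10 ms from the neighbours' median; vertices with fewer
neighbours are kept but flagged isolated.  The 10-ms tolerance is our
declared default; the radius is the clinical convention.

Interpolation: Gaussian-kernel RBF with a ridge ("smoothing") term.  The
kernel shape and ridge are selected by exact leave-one-out
cross-validation on a logarithmic grid (shape scaled to the median
nearest-neighbour spacing; ridge 1e-8 to 1e-1), using the closed form
`e_i = c_i / (A^{-1})_{ii}` so the search costs one factorization per
candidate.  Vertices farther than 10 mm from every datum are NaN —
unsupported regions stay undefined rather than extrapolated.

TAAT = distal-CS activation time − earliest valid right-atrial LAT; values
≤ 0 are reported with a non-physiological flag.  TAAT is exactly linear
under uniform slowing of the LAT field.

## 4. CV fields (`atrialep.cvfield`)

At each recording point, neighbours within 5 mm (at least 8; k-nearest
fallback) are projected onto a tangent plane from local PCA, and a
quadratic surface T(u, v) is least-squares fitted; the in-plane gradient g
at the point gives the CV vector v = g/|g|² (coordinates in mm and LAT in
ms make 1/|g| directly m/s).  Rank-deficient designs (collinear
electrodes) are skipped and flagged; gradients below 1e-3 ms/mm mean
near-simultaneous activation and an undefined CV.

Divergence: per point, each tangential CV component is fitted with a
linear model over the same neighbourhood; div = dv_u/du + dv_v/dv,
converted to 1/s.  Points with divergence strictly below −1.5 1/s are
masked as wavefront collisions (the boundary value is retained) and
excluded from interpolation and summaries.  A planar wave masks < 1% of
points; a two-wave collision produces divergence of order −100 1/s along
the collision line, so the −1.5 1/s threshold is conservative.

Summaries report median/mean/IQR and a fixed 0.05 m/s-bin histogram over
[0, 2] m/s after a 2.0 m/s physiological gate (gated counts reported).
Neighbourhood size, polynomial degree and the divergence discretization
are declared defaults — the method family fixes none of them.

## 5. Tissue simulation (`atrialep.sim`)

**Ionic model.**  The 21-variable Courtemanche–Ramirez–Nattel human atrial
model, transcribed from the published equations with analytic limits at
the removable singularities of the rate functions.  Validation: the
published quiescent state is a fixed point (drift < 0.02 mV over 1 s under
an independent stiff integrator); the paced AP shows the characteristic
spike-and-dome with APD90 ≈ 285 ms at 1 Hz (published range); the
LUT-based tissue stepper reproduces the trajectory of the directly
integrated equations on a single cell (peak within 2 mV, APD90 within
5 ms).

AF electrical remodeling multiplies g_to by 0.40, g_CaL by 0.35 and g_K1
by 2.00 (APD90 drops to ≈ 135 ms).  The BrS-like substrate applies a g_Na
factor of 0.30 to a randomly selected half of the nodes; masks flag
exactly `floor(fraction*n)` elements from a seeded shuffle.

**Monodomain numerics.**  Operator splitting at dt = 0.02 ms: explicit
anisotropic finite-difference diffusion on a 2-D grid (no-flux boundaries;
per-edge conductances; automatically sub-cycled if the explicit stability
bound requires; an error names the bound when sub-cycling is disabled),
Rush–Larsen exponential updates for the 12 voltage-dependent gates,
forward Euler for concentrations, Ca-dependent gates and the membrane
equation.  All purely voltage-dependent quantities (gate steady states,
per-step Rush–Larsen factors, current factors) are pre-tabulated on a
0.02-mV grid over [−120, 80] mV and linearly interpolated inside the
numba-compiled kernel (~125 ns per node-step on one core).

Fibres run along x.  Default diffusivities D_L = 0.3, D_T = 0.06 mm²/ms at
0.25-mm spacing give planar CV ≈ 0.87/0.40 m/s (longitudinal, AF-remodeled
tissue, g_Na ×1.0/×0.3); halving the spacing to 0.125 mm changes CV by
≈ 4.5%.  Fibrosis removes a random fraction of *transverse* edges
(electrical decoupling transverse to fibre direction); the g_Na mask is
node-wise.  Wave counting: connected components of the Vm > −60 mV node
set (4-neighbour; independent flood-fill oracle in the tests), evaluated
every millisecond.

**AF induction protocol.**  Burst pacing from a 3×3 mm patch: a train of
2-ms, 60 pA/pF stimuli whose coupling intervals decrease linearly (default
2.5 s, 200 → 125 ms — duration per the clinical protocol, the interval
ramp our declared default), then a stimulus-free observation period.
"Sustained" requires suprathreshold activity throughout the final 100 ms
of the simulation; complexity is the per-millisecond wave count averaged
over the whole post-pacing period.  Inducibility is the fraction of pacing
sites (default: an even lattice) whose run is sustained.

**Desk-scale scenario domain.**  The anatomically detailed 3-D atria of
the original experiments are out of scope; scenario comparisons run on an
idealized *cylindrical* strip (`periodic_x`): a 120-mm closed perimeter
along the fibres, 2-mm transverse extent, 0.5-mm spacing.  The closed
path is the minimal geometry on which the two requirements for sustained
macro-reentry operate — a flat desk-size sheet with no-flux boundaries
extinguishes every reentrant pattern regardless of substrate, because the
AF-remodeled wavelength (CV × refractory period ≈ 45–70 mm) does not fit
inside it.  On the closed path, induction needs (i) a unidirectional
conduction-block event during the train and (ii) wavelength < perimeter.
S1–S2 probing shows (i) is a property of the heterogeneous substrate: at
~150-ms coupling the g_Na-reduced arm conducts one way in ~70 ms and the
other way in ~200 ms, while control conduction stays direction-symmetric
at every coupling down to bidirectional block.  Requirement (ii) sets the
perimeter: 120 mm comfortably fits the slowed substrate's wavelength but
leaves the control arm unable to sustain what it cannot start.  Even in
replicates without induction, the slower, fragmenting substrate carries
post-pacing activity for longer, so its mean wave count stays above
control's.  Desk-scale diffusivities are reduced to D_L = 0.15,
D_T = 0.03 mm²/ms (planar CV ≈ 0.45 m/s, matching the 0.31–0.49 m/s
median CVs measured in mapped patients); the burst train keeps the
clinical 2.5-s duration with a 200 → 125 ms linear ramp (~5-ms
decrements, fine enough to land inside the vulnerable window), followed
by an 800-ms observation period, paced from two sites per replicate.

What passing scenario tests show: the *direction* of the substrate effect
(higher inducibility and wave count with heterogeneous Na+ loss-of-
function at matched fibrosis) on an idealized closed path.  What they do
not show: absolute inducibility rates, multi-wavelet fibrillation of
anatomical complexity, or any effect requiring realistic atrial geometry.

## 6. Statistics (`atrialep.stats`)

Welch (unequal-variance) t tests everywhere, two-sided — identical to the
pooled test under equal variances and robust otherwise; a summary-moment
variant allows checks against printed tables.  Pearson correlation with
R² (sign kept in r).  2×2 tables: chi-squared with continuity correction,
or the two-sided Fisher exact test under the standard
probability-ordering convention (validated to 1e-12 against direct
hypergeometric enumeration).  Bonferroni: min(1, m·p).  Degenerate
margins raise rather than silently returning 1; the scenario comparator
maps the all-tied case to p = 1 explicitly.

## 7. Problem sizes used by the acceptance script

`scripts/acceptance.py` regenerates everything from scratch with the given
seed: 3 planar wavefront datasets (~240 electrodes each) plus collision
and noisy variants on a 40×40 mm patch; 100 synthetic ECG patients (15 s
each); single-cell APD90 runs; a 21×21 resting sheet for 1 s; strand CV at
four g_Na factors; 3 seed replicates of the BrS-vs-control cylinder
comparison; 2000 null replicates for type-I calibration.  These sizes keep
the full script within a desktop-minutes budget while leaving every
estimate's Monte-Carlo error well inside the tolerances asserted in the
test suite.

## 8. Known limitations

* The ECG generator is additive-template based; no torso forward model,
  respiratory modulation, or heart-rate variability.
* Entropy/sample-entropy parameters are conventional defaults (10 bins;
  m = 2, r = 0.2 SD), not values fitted to any clinical dataset.
* Geodesic distances are approximated by Euclidean ones in the 2-mm
  outlier check and the RBF kernels; negligible at those radii on
  atrial-scale curvature, untested on strongly folded geometries.
* The scenario domain is a cylinder, not an atrium: inducibility numbers
  are comparable only within the package's own scenario pairs.
* Single precision of the biology: no genotype-specific kinetics, no
  autonomic or hormonal modulation.
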