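# Methods

This note documents the models behind `fluorplate`, the parameters that
matter, the numerical choices, and what the synthetic data generator
does and does not emulate.

## Light protocols

A protocol is an ordered list of constant-PPFD phases beginning with a
dark-adaptation phase (the dark-adapted Fv/Fm convention requires it).
Saturating pulses (default 5500 µmol m⁻² s⁻¹ PPFD, 800 ms) probe the
PSII state: the dark phase carries one pulse at its end, and each lit
phase carries a pulse train at a fixed interval, placed at
t₀ + k·interval for k = 1 … n with the last pulse on the phase end. A
zero interval means a single pulse at the phase end. Phase boundaries
are half-open [start, end), with the final instant of the protocol
assigned to the last phase, so `ppfd_at` is piecewise constant and
right-continuous; a pulse sitting on a boundary records the PPFD of the
phase it terminates, since its frames are captured under that light.

Two presets are built in. `fig5_steps` is a three-step quenching
protocol: 1 h dark, then 500 µmol m⁻² s⁻¹ for 15 min, 100 for 10 min
and 1000 for 10 min, pulses every 60 s (36 pulses in total). The
step-down (500→100) probes NPQ relaxation and the step-up (100→1000)
NPQ induction. `light_curve` is a dark hour followed by a configurable
PPFD ladder, default {26, 130, 260, 520, 830, 1140} µmol m⁻² s⁻¹ with
six pulses per step at 60 s; the endpoints are fixed by the screening
range of interest, the interior rungs are an even spacing choice and
fully configurable. Pulse placement at phase start is a convention of
this package (no pulse at t₀; first pulse one interval in), chosen so a
pulse never samples a freshly switched light field.

## The parameter engine

All Table-style PSII parameters are simple algebra on ROI-mean
fluorescence (see README for the list). Two points deserve notes:

* **Fo′.** Imaging systems rarely measure light-adapted minimal
  fluorescence directly (it requires a far-red interlude). The
  Oxborough–Baker estimator Fo′ = Fo/(Fv/Fm + Fo/Fm′) is used by
  default; it reduces to Fo when Fm′ = Fm and is monotone in Fm′. A
  measured-Fo′ path exists for instruments that provide one.
* **qL.** The lake-model fraction of open centres is implemented as
  qP·(Fo′/F′), which stays in [0, 1] on valid inputs. The reciprocal
  variant qP/(Fo′/F′) — which appears in some summary tables but can
  exceed 1 — is available as `variant="as_printed"` and triggers a
  range warning when it leaves [0, 1].

ETR uses a default absorptance of 0.84 (a typical healthy-leaf value;
override per dataset when absorbance has been measured) and a PSII/PSI
energy partition factor of 0.5.

Records violating Fm ≥ F are flagged (`fm_lt_f`), never clamped;
flagged records are excluded from derived tables by default and can be
propagated instead. With the Oxborough–Baker Fo′, the efficiency chain
0 ≤ Fq′/Fm′ ≤ Fv′/Fm′ ≤ Fv/Fm ≤ 1 and the identity Fq′/Fm′ = qP·Fv′/Fm′
hold exactly; both are enforced by property tests.

## NPQ kinetics

Each lit phase is one segment, classified by the sign of the PPFD step
into it (the first lit phase, dark→light, is an induction). Relaxation
segments are fitted with y(t) = baseline + a·e^(−bt), inductions with
y(t) = plateau − a·e^(−bt); both are single-exponential with one rate
per direction.

**Asymptote handling.** A pure zero-baseline decay is biased whenever
NPQ relaxes to a nonzero minimum — which it does under any nonzero
background light — so the asymptote defaults to the segment's final
observed value. Both a literal zero-baseline decay and an explicit
numeric (or, for the noiseless recovery tests, the exactly known)
asymptote are selectable. This convention makes the fit invariant to
the segment's time origin, which is also tested.

**Numerics.** Initial (a, b) come from a log-linear regression of the
positive residuals against time; the nonlinear refinement uses
Levenberg–Marquardt least squares with parameter tolerance 1e-10 and an
iteration cap of 500·n. Constant segments and segments already at or
above the plateau raise a fit error (the rate is unidentifiable);
non-monotone relaxation segments warn but are fitted. Fits whose
half-time falls below the sampling interval are flagged
`half_time_below_sampling_interval` rather than silently reported:
induction half-times of a few seconds are not resolvable from a 60 s
pulse grid, and such values should be read as extrapolations of the
model, not measurements. Resolving them properly requires a denser
pulse schedule, which the protocol module can express.

Half-times are t½ = ln(2)/b (time constant t = 1/b). The per-sample
dynamics summary reports the minimum NPQ over the low-light segment,
the maximum over the following high-light segment, the percent decrease
relative to the NPQ at the moment of the step down, the fold increase
(max/min, flagged undefined when the minimum is zero), and R50/I50 from
the fits.

## The synthetic plate

The generator exists so every downstream stage can be validated against
exact ground truth. Per genotype it takes dark-adapted Fo and Fm
(defaults 190 and 1000 counts, Fv/Fm = 0.81), a steady-state NPQ
hyperbola NPQ_ss(E) = NPQ_max·E/(E + k_NPQ), a steady-state qP decline
qP_ss(E) = 1/(1 + E/k_qP), and first-order rates b_ind and b_rel. These
steady-state forms are deliberately minimal monotone choices with the
right limits (0 and 1 in darkness; NPQ_max and 0 at saturating light) —
they are not mechanistic models of the xanthophyll cycle or PsbS
kinetics, and nothing downstream depends on their particular shape.

Within each phase the true NPQ relaxes exponentially from its
phase-entry value toward NPQ_ss(phase PPFD), using b_ind when the
target is above the entry value and b_rel otherwise; the trajectory is
continuous and starts at zero. Pulse values invert the parameter
definitions: Fm′ = Fm/(1 + NPQ), Fo′ by the same Oxborough–Baker
estimator the analysis uses (making the noiseless round trip exact by
construction — a deliberate choice, so the generator cannot be used to
measure the estimator's own bias unless an independent Fo′ is injected),
and F′ = Fm′ − qP_ss·(Fm′ − Fo′).

Three genotype presets bundle contrasting dynamics: a high-NPQ,
slow-relaxing cultivar (steady-state NPQ 0.37→2.2 between 100 and
1000 µmol m⁻² s⁻¹, R50 124.5 s, I50 5 s), a low-NPQ fast-relaxing one
(0.26→1.2, R50 67.9 s, I50 9 s) and an intermediate landrace
(0.43→1.5, R50 108.6 s, I50 4.1 s). The hyperbola constants are solved
from the two steady-state anchors; the rates are ln 2 / half-time.

Rendering places each section as a rectangle (a regular grid with
optional jitter), applies multiplicative Gaussian pixel noise
(1 + cv·N(0,1), truncated at zero; cv defaults to 0 in the library and
0.02 — a plausible well-exposed CCD figure — in the CLI) and draws
background pixels from a low-count floor (N(2, 0.8) counts, clipped at
zero). Everything is deterministic given the seed.

What the generator does **not** emulate: optical point-spread and
vignetting, leaf curvature and self-shading, within-section chlorophyll
gradients, pulse-to-pulse actinic instability, sensor dark current
drift, or any non-rectangular leaf geometry. Passing tests on synthetic
plates therefore demonstrate the correctness of the *computations*
(segmentation on well-separated sections, ROI statistics, parameter
algebra, fit recovery), not robustness to every optical artefact of a
real imager.

Datasets are written as a multi-page TIFF (pulse order, steady-state
frame before maximal frame) plus sidecar CSVs. The instrument-like
default is 16-bit unsigned counts, which rounds non-integer model
values; `dtype="float32"/"float64"` gives lossless round trips for
validation work. The reader maps pages through the metadata columns,
never by page-order assumption, and ignores unreferenced pages with a
warning.

## Segmentation and sample identity

Sections are segmented on the dark-adapted Fm frame — the
highest-signal, highest-contrast frame of the stack — by Otsu (or
fixed) thresholding, hole filling, 8-connected labelling and a minimum
area filter (recommended: half the smallest expected footprint).
Sample IDs are assigned in reading order by dividing the frame height
into equal row bands and sorting centroids by (band, column); this
matches nearest-grid-slot assignment for jitter up to roughly half a
cell and is deliberately free of clustering heuristics. Pixel
coordinates are 0-based (row, col) with origin top-left.

## Gas log QC

Chamber gases are summarised by the per-channel mean and the maximum
absolute percent deviation from it over a window (setpoint-relative
deviation is available). Switch performance is *sustained* settling
time: the time from the switch to the first sample after which every
sample in a holding window (default 300 s, truncated at log end) stays
within target·(1 ± tolerance). First crossings that immediately leave
the band do not count. On simulated first-order logs the measured time
matches the closed form τ·ln(Δx/band) to within one 15 s sampling
interval across τ = 10–60 s.

The gas simulator is a per-segment closed-form first-order response to
a switched target plus additive Gaussian sensor noise; it does not
model flow dynamics, pressure coupling or sensor drift.

## Statistics

`compare_groups` reports Shapiro–Wilk normality per group and Levene
homogeneity across groups alongside the main test, never using them to
switch tests automatically (a Kruskal–Wallis path is an explicit flag).
Two groups are compared by two-sample t test, more by one-way ANOVA
with Tukey–Kramer HSD. Letters come from an insert-and-absorb compact
letter display, lettered in order of decreasing group mean. P-values
are per parameter; no multiplicity correction is applied across
parameters by default (a Benjamini–Hochberg adjustment backs the
nonparametric pairwise path and can be applied externally to the
per-parameter results).

## Problem sizes used in the test suite

The suite validates round-trip exactness on a 25-section, 36-pulse
plate at 200×200 px, runs the full screening-scale chain once at 120
sections and 512×512 px, uses 50–200 replicates for noisy-fit bias
checks and 100 replicate experiments for the power check at n = 4.
These sizes keep the whole suite under a minute while leaving every
code path exercised at realistic dimensions; all simulations are
seeded and deterministic.

## Known limitations

* Fo′ is an estimate unless measured; qL inherits its bias.
* Single-exponential kinetics: no separation of the fast (qE) and slow
  (qT/qI) NPQ components; segments mixing both will fit an effective
  intermediate rate.
* Induction half-times shorter than the pulse interval are flagged, not
  resolved.
* Segmentation assumes sections are brighter than background and
  mutually separated by at least one background pixel diagonal-free
  gap; touching sections will merge.
* The grid ID assignment assumes one section per grid cell; missing
  sections shift IDs within their row band only if an entire band is
  empty of the expected count.
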