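# Methods

This note documents the models, estimators and design choices behind
`nbdyn`, in the spirit of a methods supplement: what is computed, under
which assumptions, which defaults matter, and what the synthetic-data
validation does and does not establish.

## 1. The simulated acquisition

The simulator emulates a confocal time series of one or two liquid-like
nuclear bodies in a dimmer nucleoplasm. All analyses operate on single
2-D planes, so the simulation is 2-D: "spherical" bodies are discs.

**Calibration.** The default raster matches the fluorescence-
fluctuation acquisition it emulates: 1000 frames of 64 × 64 pixels over
a 13.5 µm field (0.2109 µm/pixel), frame time 121 ms (64 lines ×
1.89 ms line time, rounded as the instrument prints it). Pixel centers
sit at `(index + 0.5) · pixel_size`; physical x = column, y = row.

**Particle dynamics.** `n_particles` (default 2000) independent point
fluorophores take Brownian steps with per-axis SD `√(2 D Δt)`, with
`D = D_in` inside a body and `D_out` outside. A step whose endpoint
crosses a body boundary is an encounter: it is accepted with probability
`p_exit` (in → out) or `p_enter` (out → in), otherwise the particle is
reflected specularly at the circle. Field-of-view edges reflect, so
particles are conserved exactly. An `immobile_fraction` of particles
never moves (they bleach but do not exchange).

Defaults: body radius 1.5 µm; `D_in = 0.005 µm²/s`, `D_out = 0.5 µm²/s`,
`p_exit = 0.05`, `p_enter = 1`. The interior diffusivity is chosen so
that photobleached sub-micrometre spots refill over tens of seconds,
matching the recovery timescales these gel-tending bodies display and
keeping recovery resolvable at the protocol's 5 s sampling; absolute
diffusivities, particle numbers and brightnesses are not measurements —
they are configurable model parameters chosen for qualitative fidelity.

**Initialization and burn-in.** Particles are placed at the flux-balance
partition `ρ_in/ρ_out = (p_enter √D_out)/(p_exit √D_in)` (boundary-
encounter rates scale with the step length, hence with √D). Because
rejected crossings correlate successive encounters, this heuristic is
not exact; burn-in therefore runs a minimum of 200 frames and then
continues in 200-frame blocks until the measured in/out density ratio
changes by < 2.5 % per block (capped at 4000 frames). The recorded
acquisition thus starts near the scheme's own stationary state for any
parameter set, which is what makes the partition stable (< 10 % drift
between the halves of a 1000-frame run).

**Interfacial coordination.** For an inhomogeneous Poisson field of
independent emitters the variance/mean excess is set by molecular
brightness and is spatially flat — independent particles crossing a
static boundary produce *no* boundary-localized moment signature. The
boundary signature of phase-separated bodies comes from coherent motion
of the interface itself, so the simulator models it explicitly with two
components applied to a Gaussian shell (σ = 0.25 µm) around each
boundary at render time:

* a *thermal wobble*: each frame, the whole shell is rigidly displaced
  by an isotropic Gaussian offset (SD 0.06 µm per axis);
* *excitation events*: each accepted boundary crossing excites, with
  probability 0.027, a localized radial bump (amplitude 0.6 µm, Gaussian
  arc footprint σ = 0.3 µm, exponential decay τ = 1.2 s, random sign).

Both components scale with the preset's boundary-mobility factor, and
the event *rate* is proportional to the boundary crossing flux — which
itself scales with the factor — so the factor is recoverable from the
high-ratio pixel frequency. The event parameters were fixed by
structural rules, not by the recovered fold: the excitation probability
targets a sparse stream (~6 events per 80-frame segment in a control run
at defaults, so event-free segments are rare and annulus coverage stays
in the linear counting regime), and the amplitude is large enough that
event pixels clear the detection fence by a wide margin.

**Presets.** `control` has factor 1.0; `stress` encodes an arsenite-like
five-fold reduction of boundary mobility as factor 0.2 applied to
(`p_exit`, `p_enter`) — and therefore to the crossing flux, the
excitation rate and the wobble — leaving `D_in`, `D_out` unchanged.

**Detection.** Each fluorescent particle is rendered as an isotropic
Gaussian PSF (σ = 0.21 µm ≈ 1 pixel) integrated per pixel via the
Gaussian CDF and normalized to `brightness` total expected counts per
particle per frame (default 5); a uniform background (default 2
counts/pixel/frame) is added and Poisson noise applied (16-bit counts).
With zero particles the output is pure shot noise, for which the
variance/mean ratio calibrates to 1.

**Protocols.** The photobleaching protocol records 3 pre-bleach frames
at 1.3 s, one bleach frame (each fluorescent particle inside the bleach
ROI switches dark with `bleach_probability`), then recovery frames every
5 s for 250 s; motion between the widely spaced frames is integrated at
the acquisition frame time, and the movie carries explicit timestamps.
Fusion moves two body centers together at a set closing speed; at first
contact the discs are replaced instantaneously by one disc conserving
total area (`r = √(r_a² + r_b²)`) at the area-weighted centroid —
relaxation dynamics are not modelled. The fixed-cell renderer draws
discs of known diameter and intensity in a nucleus/cell/background
geometry with independent protein, DNA-stain and RNA channels.

## 2. Moment analysis

Per segment (default 80 frames; trailing remainder dropped, so 12 maps
tile a 1000-frame run covering frames 0–959) the per-pixel mean and
*population* variance (denominator N, the number-and-brightness
convention) are computed by a shifted single-pass accumulator that
matches the two-pass computation to better than 1e-9 relative. The
ratio is defined where the mean exceeds a floor (1 count; the ratio is
unstable at near-zero mean) and NaN elsewhere. No detrending is applied
by default.

**High-ratio frequency.** The fraction of valid pixels in an analysis
region whose ratio exceeds a threshold. The adaptive ("auto") threshold
is the robust upper outlier fence of a user-supplied quiet reference
region — median + 5 × 1.4826 × MAD, estimated from the reference values
pooled over all segments of a series. A reference *percentile* was
rejected: it misclassifies a fixed fraction of quiet pixels by
construction, which floors the frequency in every condition and
mathematically caps the observable fold change between conditions
(a 5 % floor caps it near 3 regardless of ground truth); the fence
admits essentially no quiet pixels while keeping genuinely coordinated
pixels, whose excursions are many MADs out. An absolute-threshold
override is available.

**Axis profiles.** Ratio values are sampled at 1-pixel steps along a
user-defined axis by bilinear interpolation, averaged over a
perpendicular band (±2 pixels by default) with invalid pixels excluded
by weight, positions reported in µm from the first endpoint.

**Boundary experiment.** The packaged experiment measures the pooled
high-ratio frequency in the annulus `true radius ± 2 σ_PSF` with the
reference disc `r < radius − 3 σ_PSF`, on seed-matched control and
stress movies. At defaults the control/stress fold of mean frequencies
recovers the encoded factor 5 to within roughly ±30 % over 3–4 seeds
(e.g. 4.7 at seeds 1–3); single-seed folds scatter more (≈4–7) because
the stress condition counts few events per movie.

## 3. FRAP analysis

Background-subtracted ROI means per frame; when a reference ROI is
given, the trace is divided by the reference trace normalized to its
pre-bleach mean (double normalization). Percentage recovery uses the
pre-bleach mean and the *first post-bleach frame* (the bleach frame
itself is excluded; t = 0 at the first frame after it):
`R(t) = 100 (F(t) − F_post)/(F_pre − F_post)`, so R(0) = 0 by
construction and a failed bleach (F_pre ≤ F_post) is an error.

The fitted summary is the plateau A of `A (1 − e^{−kt})` (least squares;
a double-exponential option reports the summed plateau); non-convergence
falls back to the mean of the last three points, flagged. The initial
rate is the origin-anchored regression slope through the recovery values
on the 5 s grid within the first 15 s, `Σ tᵢRᵢ / Σ tᵢ²` — equal to
R(15)/15 for linear data, noise-robust otherwise; an endpoint variant is
exposed.

**Parameter-recovery design.** In a closed 13.5 µm field the bleached
molecules are a non-negligible share of the accessible pool, so the raw
plateau under-reads the mobile fraction. The packaged spot experiment
therefore follows standard FRAP practice: the analysis ROI is inset
0.15 µm inside the bleached region (PSF bleed of unbleached neighbours
otherwise contaminates the post-bleach depth), and the unbleached
remainder of the body (excluding the boundary shell) serves as the
double-normalization reference, which cancels the pool-share loss
analytically. With a 2.0 µm body, a 0.5 µm bleach spot and 12 000
particles (particle-number fluctuations in the small ROI otherwise
dominate), the fitted plateau recovers `100 (1 − immobile_fraction)`
within ±5 points as the mean of 3 seeds (per-seed scatter is ±5–10
points at intermediate fractions).

**Acute-stress experiment.** Whole-body bleaches probe exchange across
the boundary. Because the two presets have different stationary
partitions, each condition equilibrated under its own dynamics would
start from a different state; the experiment instead equilibrates both
under control dynamics and switches the mobility factor at recording
start (acute perturbation), and uses a fast-exchanging body
(`p_exit = 0.3`) so that a real nucleoplasmic reservoir exists. Stress
then strictly lowers both the fitted maximum recovery and the initial
rate in seed-matched runs.

## 4. Morphometry

Otsu thresholding restricted to the nucleus mask (fixed-value override
available), 8-connected components, holes filled, objects below
0.05 µm² removed. Equivalent diameter `2 √(A/π)` from the measured
area; size classes use closed upper bounds (d ≤ 0.75 µm → I,
0.75 < d ≤ 2 → II, d > 2 → III), resolving the overlapping printed
endpoints; a body whose *measured* diameter rasterizes just past a
boundary is classified by that measurement. Fn/c is
`(mean_nucleus − bg)/(mean_cytoplasm − bg)` with cytoplasm = cell minus
nucleus; the RNA ratio is `(F_NB − F_bg)/(F_nonNB − F_bg)` over the NB
area, the non-NB nucleoplasm and an extracellular background region.
Illumination correction divides by a Gaussian estimate of the field
(σ = width/8) and rescales to preserve the global mean. Noiseless
rendered discs are recovered within one pixel-equivalent of diameter;
with Gaussian noise at 10 % of the NB contrast, within two.

## 5. Statistics

Each group is screened with the D'Agostino–Pearson omnibus test; the
parametric branch (unpaired two-tailed t-test for two groups, one-way
ANOVA with Tukey HSD for more) is taken iff every group passes
(p > 0.05) and has n ≥ 8 (the omnibus test is undefined below that;
smaller groups route non-parametric with a note). The non-parametric
branch is Mann–Whitney U or Kruskal–Wallis with Dunn pairwise
follow-up (tie-corrected, Holm-adjusted — written in-house, as no
installed package provides Dunn's test). Marks: `*`/`#` tiers at
0.05/0.01/0.001/0.0001. Under null simulations (normal, n = 50/group,
500 repetitions) the gated procedure's type-I error at α = 0.05 lies
within [0.03, 0.07].

## 6. What the synthetic validation does and does not show

The generator reproduces the statistical *structure* the analyses
assume — partitioned diffusion, coordinated interfacial motion whose
rate scales with boundary mobility, shot-noise-limited detection,
protocol timing — with known ground truth, so passing tests establish
that the estimators recover what they claim to estimate under those
assumptions, at the stated problem sizes. It does not establish
instrument-level realism: there is no 3-D optics or scanning-line skew,
no detector gain or afterpulsing, no photophysics (blinking, triplet
states, acquisition bleaching beyond the explicit bleach pulse), no
cell-to-cell variability, and fusion omits shape relaxation. Absolute
sizes from real CellProfiler-style pipelines depend on thresholding
settings that are not recoverable; the morphometry here is a
reproducible stand-in, and absolute-size comparisons across software
should expect systematic offsets.

## 7. Problem sizes and numerical choices

The packaged experiments run at the protocol scale (1000-frame 64 × 64
movies, 55-frame FRAP protocols over 250 s, 500-replicate null
simulations); the unit-test suite uses reduced sizes of the same models
and the full scale lives in the acceptance checks. Fits use bounded
least squares (`A ∈ [0, 500]`, `k ∈ [1e-6, 100]`); ratio pixels below
the mean floor are excluded rather than clipped; ties at size-class
boundaries go to the smaller class; all random streams derive from a
single seed via independently spawned substreams (placement, diffusion,
bleaching, detection, interface), so any layer is reproducible in
isolation.
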