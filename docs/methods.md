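# Methods

## Signal model

Time-gated detection integrates the donor emission over rectangular windows
of width w (default 1000 ps) opened at delays t_g after the laser trigger.
For a single exponential of lifetime τ excited periodically with period P
(16 666.7 ps at 60 MHz) and an instantaneous response, the expected count in
gate g is

    N_g = A · τ · e^{−(t_g − t₀)/τ} · (1 − e^{−w/τ}) · W,   W = 1/(1 − e^{−P/τ}),

where A is the instantaneous intensity at the start of the decay (counts/ps
per pixel) and W sums the residual fluorescence of all earlier pulses
(geometric series; ≈0.13 % at τ = 2.5 ns and 60 MHz — small, but retained so
the model is exact rather than approximate). Multi-component decays are
amplitude-fraction-weighted sums of such terms. The two-component FRET decay
uses fractions (β, 1−β) on lifetimes (τ_DA, τ_D): β is the *amplitude*
(pre-exponential) fraction, which maps directly onto the molecular bound
fraction; the photon-count (intensity) fraction would additionally weight by
the lifetimes and is available from the fitted amplitudes if needed.

**Gate shape.** Gates are ideal top-hats. The real intensifier has a
~100 ps rise time; that distortion is absorbed into the IRF rather than the
gate model.

**IRF.** Three forms: delta (closed-form gate integrals), Gaussian
(centre, FWHM), and measured (uniform-grid trace, normalised to unit area).
Finite IRFs enter by circular convolution with the wrapped decay over one
period on an oversampled grid (default 25 ps, automatically refined to
FWHM/10 for narrow Gaussians and to the trace step for measured IRFs). The
wrapped exponential is discontinuous at the excitation instant, so the grid
carries exact per-bin averages of the exponential rather than point samples;
the resulting half-bin centring is compensated at gate-integration time.
This keeps the discretisation error second order: a Gaussian IRF narrowed to
τ/100 reproduces the delta closed form to ~3×10⁻⁵ relative at the default
step.

**Time origin.** Gate delays are measured from the trigger; all model
evaluations shift by a per-plate t₀ estimated from a reference-dye well
(rhodamine 6G; its lifetime is a required input, default 4080 ps) by
fixed-lifetime least squares over t₀ with the amplitude solved linearly.
Identifiability requires the rising edge inside a gate: if every gate lies
after the decay start, a t₀ shift is indistinguishable from an amplitude
rescale for a sharp IRF. The misfit is scanned on a coarse grid (local
minima exist at multi-hundred-ps offsets), refined by bounded minimisation,
and ties in the degenerate flat valley break toward the largest t₀ (its
upper edge). Estimates whose reduced χ² exceeds 5 are flagged and the
nominal origin kept.

**Background.** The time-varying background is one scalar per gate from a
blank (buffer-only) well: a sigma-clipped mean over pixels (clip at median +
8 Poisson sigma). A plain median would be quantised to integers on Poisson
data — up to half a count of bias, which measurably distorts t₀ calibration
when decays are summed over many pixels; the clipped mean keeps robustness
to stray bright pixels without that quantisation.

## Fitters

Both fitters exploit separability (variable projection): amplitudes enter
linearly and are eliminated in closed form, leaving a 1-D lifetime search.
Weights are Poisson, variance taken as the observed counts floored at one.

**Monoexponential (per pixel).** For each candidate τ the amplitude has a
closed-form non-negative weighted least-squares solution. A 60-point
logarithmic grid over [200, 8000] ps brackets the optimum; a vectorised
golden-section refinement (90 iterations, all pixels simultaneously)
follows, finished by a two-step parabolic vertex polish — golden-section
comparisons drift once the objective reaches its floating-point noise
floor, and the vertex fit over finite steps (0.05 then 10⁻⁴ ps) recovers
the analytic minimum essentially to machine precision, which matters for
the noiseless exactness guarantees below. Pixels with no counts above
background are flagged unfittable. With a delta IRF the basis is evaluated
in closed form; finite IRFs are pre-tabulated on a 400-point lifetime grid
and cubic-spline interpolated, so per-pixel searches never re-convolve.

**Global biexponential (per condition).** τ_D is fixed from donor-only
wells of the same plate (mean of per-pixel monoexponential lifetimes over
those cells). One shared τ_DA is searched on [200, τ_D − 100] ps (coarse
grid of 120, golden section, parabolic polish; ties toward larger τ_DA,
i.e. smaller FRET efficiency); at each candidate the two per-cell
amplitudes are solved by exact 2-variable non-negative least squares on the
normal equations. Cells whose unconstrained optimum had a negative
amplitude are marked `clipped`. β = a_DA/(a_DA + a_D) per cell; the total
amplitude a_DA + a_D is the fitted t = 0 intensity used downstream for the
donor concentration.

**Identifiability.** The fit is compared against the nested β ≡ 0 model
(every cell a pure unquenched decay). If the pooled χ² improvement does not
exceed 2·(n_cells + 1) — roughly twice the chance improvement from the
extra per-cell amplitude and the shared lifetime — the condition is
declared unidentifiable, the β = 0 solution is reported, and a warning is
emitted. Without this collapse, β = 0 data drive τ_DA to the upper search
bound where the two basis decays are collinear and the amplitude split is
arbitrary. A bound-hitting τ_DA is flagged separately.

**Weighting bias.** Observed-count weights (rather than iterated model
weights) carry a small low-count bias; at ≥10⁴ photons per decay the mean
lifetime bias is ~0.3 %, verified in the tests, and irrelevant at the
per-cell photon counts of the screening regime (~10⁵–10⁶).

## Plate analysis

Segmentation thresholds the first donor gate image at background +
5·robust-σ (MAD-based), intersected with the same rule on the acceptor
image for co-transfection conditions (cells expressing only the donor are
excluded there); 8-connected components, minimum area 100 px, border cells
excluded. Per cell: pixel count, mean background-subtracted gate-0 donor
intensity I_D, mean background-subtracted acceptor intensity I_A, the
acceptor/donor ratio I_A/I_D (only when I_D > 0), the mean pixel-wise
monoexponential lifetime, and the gate-count sums over the mask that feed
the global fit (summing maximises photons per decay; per-pixel β is out of
scope).

Interaction calling uses per-condition means of per-cell lifetimes. The
plate-level threshold is twice the largest |donor-only − negative-control|
mean-lifetime difference across donor constructs — the doubled worst-case
biological noise; a reduction equal to the threshold counts as positive
(boundary convention documented in `call_interactions`). One threshold
serves the whole plate. Per-well means and per-condition box-plot summaries
(median, quartiles, 1/99 percentiles) are both reported; the condition-level
cell mean is what drives the call.

Intensity calibrations are ordinary least-squares lines through dye-dilution
wells: donor slope c_D from the mean per-pixel fitted t = 0 intensity
(monoexponential on a pure dye), acceptor slope c_A from the
background-subtracted mean image intensity. The donor concentration uses
the *global-fit* t = 0 amplitude per cell, not total intensity and not the
mono-fit amplitude: FRETing and non-FRETing donors differ in brightness
through their lifetimes, and a monoexponential fitted to a two-component
decay misestimates the true t = 0 intensity. The acceptor uses the single
gated intensity image; no equivalent decay correction applies to it. A
`settings_tag` on each calibration curve refuses application to data
acquired under different optics (e.g. sectioned calibration on wide-field
data).

Per-cell K_D = (1 − β)(A_total − β·D_total)/β with D_total = I_D0/c_D,
A_total = I_A/c_A. Cells are excluded — flagged, never truncated, to avoid
biasing the aggregates — when β is degenerate (0 or 1), when the implied
acceptor bound fraction γ = β·D_total/A_total exceeds 1 + 0.05 (physically
impossible), or when the implied free acceptor is non-positive. Aggregates
(median and IQR; the mean is also reported) are taken over valid cells per
condition, withheld below 10 valid cells, and additionally grouped per FOV.

## Synthetic plates

The generator emulates the screening acquisition: wells with roles
donor-only / negative-control / test / blank / reference-dye / calibration,
several FOV per well, cells as non-overlapping uniform disks (radius
7–12 px, ≥6 px edge separation in a 256×256 field; sub-cellular structure
is deliberately absent because the analysis is per cell). Expression levels
d_total, a_total are drawn independently and log-uniformly over
[50 nM, 5 µM] — two plasmids do not co-express at a fixed ratio, and the
spread provides the K_D titration. The complex concentration is the smaller
root of da² − (D+A+K_D)·da + D·A = 0, evaluated in the cancellation-free
form 2p/(S + √(S²−4p)); negative controls set da = 0. Default truth:
τ_D = 2400 ps, τ_DA = 1300 ps, K_D = 500 nM. Detection: the five-gate
scheme above with true t₀ = 300 ps (the first gate straddles the decay
start, as on a real instrument — and as t₀ calibration requires), gains
c_D = 0.002 counts·ps⁻¹·nM⁻¹, c_A = 0.5 counts·nM⁻¹ per pixel, a per-gate
declining background (2.0 … 1.2 counts), and Poisson counting noise. A
median cell (~300 px, ~500 nM donor) collects ~6×10⁵ donor photons.
Intensifier gain noise is not modelled explicitly; an optional
excess-variance factor (default 1, i.e. off) inflates the Poisson variance
multiplicatively. One master seed; per-FOV streams are derived from
(seed, well, FOV index) so any FOV regenerates independently.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: optics (PSF, sectioning residuals,
vignetting), photobleaching, autofluorescence, cell-shape and sub-cellular
heterogeneity, endogenous unlabelled competitors, κ² orientation effects
and dark acceptor states. The last three bias real K_D estimates in ways no
amount of synthetic validation can bound.

## Problem sizes and numerical choices

The default simulated plate uses 8 test FOV (200 test cells), 4 donor-only
and 4 negative-control FOV at 25 cells each — enough cells that the K_D
median's sampling error (~2 %) is well inside the ±25 % recovery check,
while a full analysis runs in ~10 s. Parameter-recovery checks on the
global fit use 30 cells at 5×10⁴ photons/cell, conservative relative to the
simulated screening cells; at exactly 10⁴ photons the per-cell β standard
error is ~0.025, so worst-of-30 errors of ~0.08 are expected and only bias
(not spread) is asserted there. Noiseless end-to-end recovery is exact to
~10⁻¹³ relative; the parabolic polishes described above are what keep the
t₀ → τ_D → τ_DA → β → K_D error chain at that level, since K_D amplifies β
error by ~1/β(1−β).

## Known limitations

- Single shared τ_DA per condition: heterogeneous FRET geometries within a
  condition violate the spatial-invariance assumption and bias β.
- Amplitude-fraction β assumes equal radiative rates of FRETing and
  non-FRETing donors; quantum-yield differences fold into the calibration.
- The 2-variable NNLS is exact for the two-component model but does not
  generalise to three components (out of scope).
- Top-hat gates: strongly non-rectangular gate profiles should be folded
  into a measured IRF.
- Thresholding segmentation merges touching cells; the generator's
  separation constraint makes this rare in simulation but real confluent
  cultures would need a watershed or learned segmenter in its place.
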