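# Methods

Numerical methods and the reasoning behind the main design decisions.

## Synthetic scenes and ground truth

A scene couples an event schedule (two annotator onsets per event, consensus
= their mean, single-annotator events allowed), a biphasic haemodynamic
response, a spatial pattern and a nuisance model. The response is built from
three raised-cosine segments — rise to the peak over `t_rise`, fall to an
undershoot of `undershoot_scale × peak` over `t_fall`, recovery to zero over
`t_recover` (defaults 12.5 / 116 / 123 s, undershoot 1.5) — so the waveform
is C1 and its extrema sit exactly at the programmed knots. HbT is always
HbO + HbR, never parameterized separately.

Rendering inverts the analysis chain: concentrations map to ΔOD through the
channel-wise MBLL, or through the same stacked multispectral Jacobian the
reconstruction inverts; intensity is `baseline · exp(−ΔOD)` with
multiplicative log-normal noise (strictly positive by construction). Nuisances
are added as channel-space concentrations (linear drift, cardiac sinusoid),
as a multiplicative intensity step on selected channels, and as dead channels
replaced by a tiny noise floor. The exact waveforms, onsets and parameters
are stored in the bundle's `truth` group so recovery tests never re-derive
them. EEG-side annotations and sync pulses are shifted by a clock offset; the
aperiodic sync-pulse pattern makes the pairing between the two instrument
clocks unambiguous, and `align_clocks` recovers the offset by a robust
least-squares match.

## Preprocessing

- **Channel pruning** flags channels whose mean intensity falls below 1% of
  the per-wavelength median (or explicit thresholds). Pruning only flags;
  data are never modified, and downstream stages zero or skip excluded
  channels. Analysis halts if every channel is excluded.
- **Step-artifact correction** estimates the jump at the largest
  first-difference inside a user-declared window by evaluating two one-sided
  smoothing splines (30 s of context each side) at the jump time and
  subtracting their difference from the trace after the jump. Smoothing
  splines, rather than polynomials, track slow physiology without chasing
  noise; the estimator is idempotent and exact for a pure step.
- **Filtering order**: the step artifact is multiplicative in intensity, so
  both the spline correction and the 5th-order zero-phase Butterworth 1 Hz
  low-pass are applied to *log-intensity*, where the artifact is additive and
  positivity is preserved when exponentiating back. Filtering raw intensity
  instead could produce negative values near sharp artifacts.
- **Optical density** is −ln(I / Ī) against the temporal mean reference.
  Excluded channels are zeroed; non-positive samples on retained channels
  raise an error naming the channel.
- **EEG** gets a clinical 0.3–70 Hz band-pass (order 4, zero phase) plus a
  50 Hz notch (Q = 35); sampling below 256 Hz is rejected.

## Haemoglobin conversion

The MBLL solves the 2×2 extinction system per channel:
ΔOD(λ) = d · DPF · [ε_HbO(λ) ΔHbO + ε_HbR(λ) ΔHbR], with d the
source–detector separation and DPF = 4.9. The shipped extinction table uses
standard compiled molar extinction coefficients for oxy- and
deoxy-haemoglobin at 1 nm resolution around 780/850 nm (natural-log
convention, µM⁻¹·mm⁻¹); its condition number at the default wavelength pair
is ~7, and a singular pair is rejected. The inverse is exact, so the
round-trip error is at machine precision.

## Forward model

### Meshes

Slab meshes are tensor grids split into six Kuhn tetrahedra per cell, so the
mesh volume equals the box volume exactly and grading (fine near optodes,
geometric growth to the far walls) is trivial. Hemisphere meshes are built
from a jittered interior lattice plus Fibonacci boundary points, Delaunay
tetrahedralized, with layers (extracerebral 5 mm, CSF 2 mm, grey 4 mm, white
interior) labelled by depth and the grey-matter surface extracted for
projection. Per-tissue optical properties ship as a CSV of adult literature
values (infant-specific compilations are not available and infant values are
generally taken to be similar); they are fully overridable.

### FEM

The continuous-wave diffusion equation −∇·(D∇Φ) + µa Φ = q is discretized
with P1 elements and a Robin (partial-current) boundary term Φ/(2A) with the
internal-reflection parameter A from the Groenhuis/Egan–Hilgeman polynomial
fit (A ≈ 3.25 at n = 1.4). Sources and detectors are point loads placed one
transport mean free path (1/µs′) beneath the optode along the inward normal.
One sparse LU factorization is shared across all sources and detectors, and
solutions are rejected if the relative residual exceeds 1e-10.

### Exact semi-infinite oracle

The solver is validated against the *exact* Green's function of the Robin
half-space problem, evaluated as the real source plus its positive plane
image minus an exponentially weighted line of image sinks behind the boundary
(weight scale z_b = 2AD), integrated with 64-point Gauss–Laguerre quadrature.
The classical extrapolated-boundary two-source "image" formula is also
provided but runs 3–5% high at 20–40 mm separations for this refractive
mismatch, which is larger than the FEM discretization error; using the exact
kernel lets the acceptance check assert ≤ 3% (measured ≤ 0.5% at 1 mm
near-optode edges). Both forms were cross-checked against a direct Hankel-
transform evaluation of the boundary condition.

### Adjoint Jacobian

The absorption Jacobian ∂(ΔOD_channel)/∂µa_node is assembled by the adjoint
(Rytov) method from products of source and detector fluence fields. The
perturbation matrix uses the *same* P1 quadrature as the FEM mass term
(exact integrals of triple products of barycentric coordinates), so the
adjoint Jacobian is the exact derivative of the discrete forward model: the
finite-difference comparison agrees to ~0.02% on the 50 largest entries, far
inside the 5% acceptance bound, and the residual difference is purely the
finite-difference step error.

## Reconstruction

The two single-wavelength Jacobians are stacked wavelength-major and scaled
by the extinction coefficients into one system mapping stacked
(ΔHbO, ΔHbR) node vectors to all-channel ΔOD. Each frame is inverted with
the minimum-norm Tikhonov solution x = Sᵀ(SSᵀ + λ²I)⁻¹y with
λ = 0.01·σ_max(S) (dense SVD on small systems, Lanczos estimate on large
ones). The Gram matrix is only (2·channels)², so one Cholesky factorization
is reused across all frames. Frames are baseline-referenced (temporal mean or
an explicit pre-onset window) and down-sampled to 1 Hz after the upstream
1 Hz low-pass. Volume images are projected to the grey-matter surface by
averaging volume nodes within 3 mm of each surface node; empty surface nodes
are NaN-flagged.

## Event analysis

Global (channel-averaged) HbO/HbR/HbT traces are linearly detrended and
referenced per event to the mean of the 60–30 s pre-onset window. The raw
phase rules are: HbT max = argmax in the first 60 s post-onset; min = argmin
between the max and the search boundary; recovery = first post-minimum time
where the 30 s moving-window slope magnitude stays below 10% of the event's
peak-to-trough range per 100 s for 30 consecutive seconds. The search
boundary is the next event's onset; phases whose defining feature is not
reached before it are flagged non-estimable and censored, never extrapolated.
`dot_event_duration` is the nan-sum of the estimable phases.

**Template refinement.** The raw rules decide responsiveness and censoring,
but their point estimates are noise-limited: the biphasic waveform is flat
(C1) at its knots, so realistic noise moves the raw argmax/argmin by several
seconds, and the slope gate fires slightly before the true end of recovery
even at zero noise. The timings are therefore refined by least-squares
fitting of the full biphasic template (parameters: onset shift, amplitude,
undershoot ratio, three phase durations, plus constant and linear nuisance
terms that absorb detrending residue). When the trace passed through the
known 1 Hz low-pass, the same filter is applied to the model inside the fit
so the filter's smoothing cannot bias the knots. A refined phase replaces the
raw one only when it stays within a guard band (10/20/25 s) of its raw
initialization, so non-biphasic or overlap-contaminated events keep their
raw, censoring-consistent values. This is matched estimation against the
declared signal model; with it, zero-noise recovery is exact to ~1e-6 s and
1%-noise recovery is within ~0.5 s.

The hemispheric comparison is a paired two-sided t-test on left/right channel
band powers; zero-variance differences raise a dedicated error rather than
returning an undefined statistic. Reports render the event-table CSV, the
global trace figure, per-event image grids at six named time points (30 s
pre-onset, onset, max, max/min midpoint, min, recovery) and a JSON summary.
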