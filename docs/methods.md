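# Methods

This note records the models implemented in `trfnirs`, the assumptions
behind them, the parameter defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Paradigm and theoretical activation model

A question run is a block design: `lead_in_rest_s` of rest, then
`n_cycles` cycles of `task_s` motor imagery followed by `cycle_rest_s`
rest, sampled at `frame_interval_s`. Defaults (30 s, 5, 30 s, 30 s, 0.3 s)
give 1100 frames over 330 s with 500 task frames. Block boundaries use
half-open `[start, end)` intervals so no frame is counted twice; the frame
at t = 0 belongs to the lead-in. The cycle count is configuration, not a
constant, so shorter protocols can be explored.

The theoretical activation model is the task boxcar convolved with a
canonical double-gamma hemodynamic response function (peak gamma shape 6,
undershoot shape 16, undershoot ratio 1:6, all with 1 s scale; kernel
truncated at 32 s). This is the field-standard HRF parameterization; the
regressor is normalized to unit peak so simulated activation amplitudes
are expressed directly in signal units. The convolution introduces the
expected ~5 s vascular lag and dispersion relative to the boxcar.

## Synthetic moment-level signals

Activation runs are

    series = A · (boxcar ⊛ HRF) + Σᵢ aᵢ sin(2π fᵢ t + φᵢ) + ε,

with physiological frequencies f = (0.1, 0.2, 1.0) Hz (Mayer waves,
respiration, cardiac), random phases per run, and white Gaussian noise ε.
Rest runs set A = 0. The training corpus is 50 activation + 50 rest runs
(100 data sets) with noise SD drawn uniformly from [1, 10] per run — the
distribution over that range is a package choice, as is the activation
amplitude A = 5 and the physiological amplitudes (1, 1, 1), all in the
same arbitrary units as the noise SD; each corpus records its per-item
seeds so any run can be regenerated exactly. The physiological sinusoids
are present in both classes (background physiology does not switch off
during imagery). The 1 Hz cardiac line is representable at the 300 ms
frame interval (Nyquist 1.667 Hz); no anti-aliasing is applied because the
signal is generated directly at the frame rate.

What the generator does **not** emulate: serially correlated (1/f)
physiological noise, task-correlated systemic physiology (blood-pressure
or breathing responses to effort), superficial-layer contamination
specific to continuous-wave measurements, inter-channel correlation, and
instrument drift. Passing tests therefore demonstrate correctness of the
pipeline's transforms and internal consistency of the decoding chain under
the stated noise model — not clinical performance on patient data.

## Photon transport and DTOF-level recordings

`transport` implements a time-domain Monte Carlo random walk in a layered
slab with isotropic scattering at the reduced scattering coefficient
(similarity relation), refractive-index-matched boundaries (a photon
reaching the surface exits), and a semi-infinite substrate below the
nominal stack carrying the deepest layer's optical properties. Path length
is accumulated per region, so the nominal layers keep their literal
0.2 cm extent and the substrate is bookkept separately. Absorption is
handled entirely by path-length reweighting, w = exp(−Σ μₐ,ₖ Lₖ): one
photon set serves every absorption setting — baseline DTOFs, per-frame
hemodynamic changes, and sensitivity factors all reuse the same paths,
which makes finite-difference derivatives nearly noise-free (correlated
estimator).

Defaults: 10 layers × 0.2 cm, μₐ = 0.17 cm⁻¹, μs′ = 10 cm⁻¹, n = 1.4
(literature-typical adult head values — the instrument papers state none,
so these are explicit configuration); detection annulus 3 ± 0.5 cm;
repetition window 12.5 ns (80 MHz) with 16 ps bins; photons arriving later
than the window are dropped, not wrapped. Detected fractions are ~2–3%,
so 10⁶ launched photons give ~2×10⁴ detected paths (weighted effective
sample ≈ 2×10³ under baseline absorption).

The analytic reference is the semi-infinite time-domain diffusion
reflectance with an extrapolated boundary (isotropic source at one
transport mean free path, A = 1 for matched boundaries), integrated over
the same detection annulus and time window as the Monte Carlo. Because a
global absorption change multiplies the reflectance by exp(−Δμₐ·v·t), the
derivative identity ∂⟨t⟩/∂μₐ = −v·Var(t) holds exactly in both the
closed form and the reweighted Monte Carlo, which the tests exploit.
Agreement of the derivative is 1–2% at 10⁶ photons for the default optics
(μs′·ρ = 30, comfortably in the diffusion regime).

A DTOF-level recording reweights the bank per frame: the intracerebral
layers' μₐ(λ) is baseline plus the extinction-weighted (ΔHbO, ΔHbR) of
that frame, the weighted histogram is scaled so the baseline expectation
equals `photons_per_frame`, and counts are Poisson-sampled. All four
channels share the same nominal geometry and hence the same photon bank,
receiving independent shot noise; this matches the cross-probe layout
where every detector sits 3 cm from the central emitter.

## DTOF moments

Moments are computed per frame over an integration window. The default
window rule (1% of peak on both flanks after subtracting a constant
background estimated from the first 10% of bins, floored at zero) follows
common practice for measured histograms with a dark-count floor. For
simulated recordings the pipeline helper defaults to full-window
integration instead: the simulator adds no dark background, the
sensitivity factors are full-window derivatives, and window truncation
would only bias the recovered absorption scale (the CNR and correlation
features are scale-invariant either way). Both rules are explicit
configuration surfaced in `IntegrationLimits`.

Only Δ⟨t⟩ — the change of the first moment relative to the mean over the
lead-in rest window — is carried into the conversion; N and V are computed
and reported but unused downstream.

## Conditioning chain

Fixed order: MARA → band-stop → detrend (each stage configurable).

**MARA.** Frames whose moving SD (window 2 s) exceeds 3× the run-median
moving SD are flagged; runs closer than one window merge into segments,
padded by half a window. Within a segment a smoothing spline estimates the
artifact trend; its residual budget is scaled by the *clean* noise level
(the run-median moving SD), not the artifact-inflated segment variance, so
the spline follows the excursion and subtracting it removes the artifact.
The corrected segment is tied to the level of the preceding ~6 s (three
windows — long enough to average out the 0.1 Hz Mayer wave), and the
subsequent frames are re-leveled only when a discontinuity larger than 3
standard errors of the level estimate remains, so baseline-shift artifacts
are removed while spike corrections never inject noise-level steps into
untouched data. Artifact-free series pass through bit-identically.

**Band-stop.** Butterworth band-stop, 0.08–1.5 Hz, applied
forward–backward (zero-phase) so block timing is preserved for the
correlation feature. Order 5: after the forward–backward pass this yields
≥ 20 dB rejection at the 0.1 Hz Mayer line (the binding constraint; an
order-4 design reaches only ~19 dB there) while leaving the 1/60 Hz task
fundamental attenuated by < 10⁻⁵ dB. One wide band-stop is used rather
than cascaded notches; the stop band must lie below the 1.667 Hz Nyquist
frequency, which 1.5 Hz does.

**Detrend.** Least-squares polynomial removal, order 1 by default
(configurable to 3): "slow drift" is read as a linear trend at the 330 s
run length.

## Sensitivity factors and hemoglobin conversion

SF_k = −∂⟨t⟩/∂μₐ,ₖ is estimated by central finite differences
(Δμₐ = ±0.005 cm⁻¹) on shared photon paths; the Monte Carlo standard
error per layer is the delta-method error of the paired ratio estimator,
computed from per-photon influence values (validated against the
empirical seed-to-seed spread). Layer indexing is 1-based from the
surface, so "layers 5–10" span 0.8–2.0 cm; the description of that span
as "below 1 cm" is approximate and the explicit indices are followed. The
intracerebral SF is treated as wavelength-specific but time-constant
(baseline linearization), and one SF is shared across the four channels
(identical nominal geometry). The substrate's own sensitivity (~4% of the
layer total for default optics) is reported separately and excluded from
the intracerebral sum, which keeps the simulated ground truth (driven
through layers 5–10 only) and the recovery unbiased with respect to each
other.

Conversion: Δμₐ(λ) = −Δ⟨t⟩(λ)/SF(λ) (an absorption increase removes late
photons and shortens ⟨t⟩, hence the sign), then per frame
[ΔHbO; ΔHbR] = E⁻¹ [Δμₐ(760); Δμₐ(830)] with E from the standard
compiled hemoglobin extinction spectra (OMLC): ε(760) = (586, 1548.52),
ε(830) = (974, 693.04) M⁻¹cm⁻¹ (decadic), converted to natural-log
μM⁻¹cm⁻¹ internally. The matrix condition number (≈3.4) is checked and an
ill-conditioned table is rejected.

## Detection and answer rule

Features per channel: CNR = (mean task − mean rest)/SD(rest) over the
timeline masks, and Pearson r against the boxcar ⊛ HRF regressor. The
detector is an RBF support-vector machine over standardized (CNR, r),
C = 1, gamma = "scale", trained on the 100-run corpus passed through the
same conditioning chain used at decoding time. A channel counts as
activated only if the SVM votes for the activation class *and* its CNR is
positive — the target response is an oxyhemoglobin increase, so a
deactivation pattern must not drive a "yes". One shared model serves all
four channels. The answer is "yes" iff ≥ 1 channel is activated; summary
CNR/r average over activated channels for a "yes" and over all channels
for a "no". Cycle-averaged reporting folds the series over the 60 s cycle
(mean ± SEM across the five cycles); the lead-in rest is dropped by
default and can be folded in on request.

In the synthetic decoding study a "yes" trial carries the activation in
all four channels (shared imagery driving the whole motor-planning patch)
and a "no" trial in none; with the any-channel rule the binding constraint
is the per-channel false-positive rate, which the conditioning chain keeps
at the percent level for noise SD ≤ 5.

## Problem sizes and numerical choices

- Monte Carlo: 10⁶ launched photons for the homogeneous physics checks,
  5×10⁵ per wavelength for the layered head model; chosen so the
  diffusion comparison resolves at the few-percent level while a full test
  run stays around a minute.
- DTOF recordings: 10⁶ expected photons per 300 ms frame (a realistic
  count-rate scale for time-resolved instruments), 1100 frames, 781 bins.
- Hemoglobin ground truth for recovery studies: ΔHbO peak 1 μM,
  ΔHbR −0.3 μM — typical magnitudes for a cortical motor-imagery
  response seen through the scalp.
- Finite differences: Δμₐ = ±0.005 cm⁻¹ balances truncation against
  round-off; halving it moves the factors by ≪ 1 SE.
- Degenerate inputs raise typed errors (all-zero DTOF window, zero rest
  SD, zero-variance series, singular extinction matrix, empty decision
  set) rather than propagating NaNs.

## Known limitations

- The transport model is a slab with isotropic scattering; no curvature,
  no CSF low-scattering channel, no anisotropy factor g, no instrument
  response function. The diffusion cross-check inherits the same
  geometry, so agreement does not validate against curved-head effects.
- Scattering-coefficient changes (ischemia, hematoma) are out of scope;
  only absorption is dynamic.
- The detector's reported accuracies are measured on the synthetic
  corpus's noise model; they are engineering gates for the pipeline, not
  claims about patient-level sensitivity or specificity.
- MARA's detector is amplitude-based; slow, low-amplitude motion drifts
  below the 3× moving-SD threshold are left to the detrending stage.
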