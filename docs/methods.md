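# Methods

This note documents the models, conventions, and numerical choices in
`pavis`, and what its synthetic data can and cannot establish about real
acquisitions.

## Forward model (synthetic acquisitions)

The generator emulates a 256-element linear array (0.09 mm pitch,
23 mm aperture, 21.33 MHz center frequency, 15–29 MHz bandwidth,
96 MHz sampling, 1538.5 m/s assumed sound speed) receiving from point
absorbers that stand in for methylene blue in the ureter lumen and the
adventitia lining it. Element `e`'s RF line is

    s_e(t) = Σ_k a_k / max(r_ek, 1 mm) · p(t − r_ek / c) + n(t)

with `r_ek` the absorber–element distance, `p` a Gaussian-windowed
sinusoid at the center frequency, and `n` white Gaussian noise of
standard deviation `noise_sigma`. Deliberate simplifications: single
scattering, lossless homogeneous medium, omnidirectional point sources
and point receivers, 1/r spreading only, one-way (receive-only)
propagation since photoacoustic sources emit at `t = 0`. This is the
simplest physics for which delay-and-sum is a consistent approximate
inverse; the package tests the analysis chain, not acoustic realism.

Numerical details:

- The pulse's Gaussian window sigma (≈ 26.7 ns) is set so the −6 dB
  amplitude spectral half-width equals half the stated 14 MHz bandwidth.
  The window is truncated at ±6σ so superposition is exactly linear in
  absorber amplitude (no subnormal tails).
- The 1/r amplitude is clamped at r = 1 mm to avoid the near-field
  singularity.
- Simulation fails loudly if any absorber's time of flight to any
  element exceeds the sampled window; note the window must cover the
  *slant* distance to the far elements, not just the target depth.
- Default `n_samples = 1280` covers ≈ 20.5 mm one-way at 96 MHz.

Ground-truth masks: the lumen mask rasterizes the configured ellipse or
rectangle; the signal mask dilates the absorber pixel footprint by one
resolution cell (one wavelength ≈ 0.072 mm, converted separately to
axial and lateral pixels).

## Image formation

- Receive-only DAS with delays `sqrt(z² + (x − x_e)²)/c`, linear
  interpolation of channel samples, zero contribution outside the
  recorded window, uniform apodization over the full aperture, no
  f-number gating (both exposed as options).
- Pixel grid: one lateral column per element (the element centers) and
  axial spacing exactly `c/fs`; this is the data's natural sampling and
  makes a 3 mm × 0.6 mm ROI 33 × 37 pixels.
- Envelope = magnitude of the analytic signal (Hilbert transform) along
  depth, per lateral line.
- Normalization to the brightest pixel per image, then amplitude dB
  (`20·log₁₀`) clipped at the display dynamic range. An all-zero frame
  is an error, not a silently black image.
- An optional zero-phase Butterworth bandpass over the transducer band
  is available and off by default.

## Frame selection

A frame is retained when its photoacoustic signal mask intersects the
ureter mask in at least one pixel (`min_overlap_px` option, default 1).
"Stationary duplicate" is operationalized as: signal-mask IoU with the
previous unflagged frame above 0.95 AND Pearson correlation of the two
envelopes inside the mask union above 0.99. Comparing against the
previous *unflagged* frame makes flagging idempotent. A manual exclusion
list (by frame id) is honored for cases the heuristic cannot see, e.g.
reverberation copies at depth.

## ROI placement

The search region is the intersection of the ureter and signal masks;
the brightest envelope pixel in it seeds the target ROI (ties broken by
smallest row, then column — exactly NumPy's row-major argmax). The
greedy walk evaluates the eight one-pixel offsets in the fixed order
left, right, proximal, distal, left-proximal, left-distal,
right-proximal, right-distal, and takes the first admissible move
(in-bounds, brightest pixel retained, mask intersected) that strictly
increases the in-mask pixel count. Strict improvement guarantees
termination; a stall or an infeasible instance (checked exhaustively
with a summed-area table before walking) raises a "no valid ROI" error
and the frame is dropped — mirroring how frames without a valid ROI are
excluded from analysis. Even-sized ROIs center with the extra pixel
toward the larger index. The background ROI reuses the target's rows and
places its right edge 0.54 mm (6 pixels at 0.09 mm pitch) from the right
image edge; it never overlaps the target when the ureter mask stays in
the left two-thirds of the image.

## Metrics

Contrast, SNR, and gCNR are computed on pre-log normalized envelope
amplitudes. Conventions the definitions leave open:

- Standard deviation: sample convention (n − 1 denominator).
- gCNR histograms: 256 equal-width bins spanning [0, 1] (the natural
  support after per-image max normalization); amplitude 1.0 falls in the
  last bin. Binning can only merge probability mass, so the binned gCNR
  is bounded above by the exact empirical overlap complement — this is
  regression-tested.

## Statistics

Shapiro–Wilk and Kruskal–Wallis delegate to SciPy (tie-corrected H,
chi-square reference with k − 1 degrees of freedom); Dunn's post-hoc z
test is implemented here with the tie-corrected pooled-rank variance.
Dunn p-values are unadjusted by default, with a Bonferroni switch, and
the report states which mode was used. Quartiles use linear
interpolation between closest ranks; whiskers are Tukey 1.5·IQR.
Significance labels use strict inequalities (p = 0.05 is "ns").
Frames within a time point are treated as independent samples. Groups
that end up with fewer than three retained frames are omitted from the
group comparison (and remain in the metrics table).

## Pipeline and the demo conditions

The demo configuration emulates the study structure at desk scale: six
time points (10–80 min), signal amplitude peaking at 20–30 min
(relative amplitudes 0.3, 1.0, 0.8, 0.5, 0.3, 0.55), five frames per
time point plus one injected stationary duplicate and one off-target
frame each, a 128-element / 11.52 mm sub-aperture, and an 832-sample
window (≈ 13.3 mm) — sizes chosen so a full run completes in well under
a minute on one core while every selection and placement branch is
exercised. The phantom is an elliptical lumen (2.2 × 0.9 mm half-widths,
80 interior absorbers) with a 10-absorber adventitia band at 0.6
relative amplitude and channel noise σ = 0.12, which yields per-frame
contrasts of roughly 1–12 dB — the order of magnitude reported for dye-
enhanced ureter imaging in vivo. Per-frame randomness derives from a
single master seed through `numpy.random.SeedSequence`, making entire
runs byte-reproducible.

## What passing tests do and do not show

The synthetic generator shares the geometry and statistics that the
analysis chain actually consumes (time-of-flight structure, amplitude
ordering across time points, mask topology, duplicate injection), so
passing tests validate the *chain*: beamforming localizes sources,
selection retains the right frames, ROI placement satisfies its
invariants, metrics match closed forms, and the rank tests are
calibrated. It does not emulate element directivity, frequency-dependent
attenuation, acoustic clutter, fluence heterogeneity, tissue motion, or
manual segmentation error — so test results say nothing about absolute
image quality values achievable in vivo, and the in vivo medians
reported for real acquisitions are not reproduction targets here.

## Known limitations

- The greedy ROI walk can stall on feasible but tortuous masks (the
  frame is then dropped); the exhaustive feasibility check prevents
  false "no valid ROI" errors but not conservative drops.
- The duplicate heuristic only catches *consecutive* near-identical
  frames; temporally separated repeats pass.
- The dosimetry helpers implement top-hat beam and fixed lumen-volume
  assumptions; systemic concentration estimates require a caller-supplied
  distribution volume.
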