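# Methods

## The measurement

A FRET sensor for MMP activity — donor (SFGFP), MMP-cleavable peptide,
acceptor (mRFP) — is tethered into a PEG hydrogel. Under 80 MHz pulsed
two-photon excitation (12.5 ns repetition period), TCSPC records each
detected photon's arrival time relative to the pulse. While the sensor is
intact, FRET shortens the donor lifetime (τ_DA); cleavage restores the
unquenched lifetime (τ_D). Lifetime is independent of fluorophore
concentration, excitation intensity and photobleaching, which is what makes
it a clean activity readout inside a scattering, inhomogeneous gel.

## Decay model and estimator

Each analysed decay is a histogram of photon counts over uniform time bins
spanning one repetition period. The model is a mono-exponential with a
constant baseline,

    f(t) = Z + A·exp(−t/τ),

evaluated at bin centres and fitted from the peak bin onward (tail fit; no
instrument response function is modelled, so the rising edge carries no
usable shape). Parameters: Z, the baseline in counts/bin (uncorrelated
background such as dark counts); A, the amplitude extrapolated to t = 0 in
counts/bin; τ, the lifetime in ns.

Fitting is Levenberg–Marquardt least squares (`scipy.optimize.least_squares`,
`method="lm"`, analytic Jacobian), with a derivative-free start: Z₀ from the
mean of the last 10% of bins, τ₀ from the time for the decay to fall to
Z₀ + (peak − Z₀)/e, A₀ from the peak corrected back to t = 0. Convergence is
relative parameter/cost change below 1e−8 within 500 model evaluations;
non-convergence returns the last iterate flagged `converged=False`.

Two weighting schemes are exposed:

- `"poisson"` (default): model-based Pearson weights, residuals scaled by
  1/√max(f̂(t), 1), iterated three times from the unweighted solution
  (IRLS). For counting noise this is close to maximum likelihood. At the
  10,000-photon gate with 256 bins it delivers a median |τ̂−τ|/τ of
  0.8–1.4% across τ = 1.5–3 ns.
- `"none"`: plain unweighted least squares on counts, the textbook LM pixel
  fit. It is less efficient when most tail bins are nearly empty (median
  error 1.5–2.5% under the same conditions, degrading with longer τ as the
  window captures less decay). It is retained both as the strict classical
  method and because the grid-search cross-check (below) profiles exactly
  this objective.

Weighting by *observed* counts (1/max(y,1)) was evaluated and rejected: it
over-weights downward-fluctuating low-count bins and measurably biases τ̂
(~3% median error at τ = 1.5 ns under the gate conditions).

The fit is cross-checked against an independent profiled grid search: for
each candidate τ, Z and A enter linearly and are solved in closed form, and
the residual sum of squares is minimised over τ by coarse grid plus bounded
refinement. LM (unweighted) and the oracle agree to ≤0.001 ns on noisy
histograms; on noiseless model-generated histograms the fit recovers
(Z, A, τ) to ≤1e−6 relative.

## Lifetime maps, gating and FRET efficiency

Images are pooled into square spatial bins (default 35×35 px, matching
standard pixel-fitting practice); incomplete edge bins are discarded, not
padded. A bin is fitted only if its pooled photons reach the gate
(default 10,000 counts, inclusive at the boundary); invalid bins carry NaN,
never 0, and the bulk "mean lifetime" is the unweighted arithmetic mean of
valid bins (bins are not weighted by photon count — each bin is one
measurement of the field). Heatmaps use the red-long/blue-short convention
with a distinct grey for missing data.

FRET efficiency is computed from donor lifetimes as E = 1 − τ_DA/τ_D.
For the sensor's nominal lifetimes (1.88 ns quenched, 2.35 ns donor-only)
this gives E = 0.200. The intensity route (acceptor:donor mean ratio after
background offsets) is provided for cross-validation.

## Peri-cellular ring profiling

In two-photon FLIM of sensor hydrogels the gel fluoresces and cells appear
dark. The pipeline: (1) project to total intensity and invert/normalise
(out = 1 − in/max) so the cell becomes the bright object; (2) white top-hat
(input minus opening with a disk) to suppress large-scale background;
(3) Canny edge detection with hysteresis thresholds expressed as fractions
of the maximum gradient of the smoothed image; (4) bridge edge gaps by
dilation, fill the interior, undo the dilation by erosion *after* filling
(so bridges cannot re-open), keep the largest component — its outline is
the primary contour; (5) label each outside pixel with contour index
k iff its Euclidean distance to the mask lies in (k−1, k]; (6) pool
contours in groups of 4 (laser spot ≈ 4.7 px) into ring bins, sum all
member pixels' histograms per ring bin, gate, and fit one decay per bin.

Contour propagation is implemented as distance-transform banding rather
than literally marching unit normals from the primary contour: for smooth
convex contours the two are identical, and banding remains well defined at
concavities, where normals collide (each pixel is assigned to its nearest
boundary point). The implementation (`scipy.ndimage.distance_transform_edt`
+ ceiling) is verified against a brute-force exact-distance oracle on
convex and concave masks.

Default image-processing parameters — Gaussian σ 3.0, hysteresis fractions
0.15/0.3, top-hat radius 15 px, closing radius 2 px — were chosen for
photon-limited intensity projections: at realistic budgets
(100–300 photons/px) the pixel CV is ~6–10%, and with light smoothing the
fraction-of-max-gradient thresholds latch onto shot-noise gradients;
σ = 3 suppresses those while the near-total-contrast cell edge survives
(mask IoU ≈ 0.96 against ground truth across rates and cell sizes). All
parameters are overridable per run in the YAML config.

A bulk peri-cellular lifetime pools all photons across the first
40 contours into a single fit; pooling is associative, so this equals the
fit of the summed ring-bin histograms.

## Statistics

Two-group comparisons use the unpaired two-tailed t-test, Student's pooled
variant by default (the common Prism-style default) with Welch behind a
flag; significance at α = 0.05. Radial gradients are summarised per cell as
the OLS slope of τ on ring-bin index over valid bins (≥3 required, invalid
bins dropped listwise); groups of cells are compared primarily by a t-test
on per-cell slopes — matching how per-group mean ± SD profiles are
plotted — with a pooled OLS interaction model (τ ~ ring + group +
ring×group) reported alongside, since "regression analysis" admits either
reading. Time-course convergence scans t-tests of each timepoint's
replicates against a reference group and reports the earliest p > α, with
the full p(t) trace. All p-values are raw; no multiple-testing correction
is applied (none is standard for these one-at-a-time comparisons).

Calibration, measured by simulation at the ring-profile level (each
ring-bin τ̂ fitted from a Poisson histogram at 10⁵ photons): under the null
(two groups of 15 flat-field cells, 500 replicates) the slope t-test
rejects at 3–7% for α = 0.05; with a 0.01 ns/px gradient injected into one
group, power exceeds 0.8. These simulations use the unweighted fit: the
calibration is a property of the between-cell statistics (slopes remain
iid across cells under the null for either weighting), and the single-pass
fit keeps 150,000 fits tractable.

## Synthetic data

The generator emulates the acquisition conditions end to end, with full
ground truth:

- **Decays**: photon totals are Poisson; each photon is uniform background
  with probability `background_fraction`, otherwise an exponential arrival
  time conditioned on [0, window) (truncation, not wrap-around — the
  baseline Z absorbs late photons). Defaults: 12.5 ns window, 256 bins.
- **Mixtures**: each signal photon draws the cleaved lifetime with
  probability `cleaved_fraction`, else the uncleaved one; the endpoints
  reduce bit-identically to single-lifetime simulation under the same
  seed. A first-order surrogate f(t) = 1 − exp(−kt) supplies cleavage
  time courses.
- **Scenes**: an elliptical dark cell (interior rate a few % of the
  hydrogel rate) in a bright gel, with τ either constant or a radial
  function of distance from the cell boundary. Per-pixel, per-bin counts
  are drawn as independent Poisson variates around the expected histogram
  (the exact thinning of the photon-level process) in one vectorised pass
  from a single seeded generator, making scenes reproducible independent
  of traversal order. Scene defaults (hydrogel 250 photons/px, interior
  5% of that, 120×120 px) are this package's choices of a realistic
  photon budget for a 300 s acquisition; no background fraction is added
  by default.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: instrument response convolution (real
rising edges are finite), detector afterpulsing and pile-up,
multi-exponential autofluorescence, depth-dependent scattering, spatially
structured background, cell movement during acquisition, and multi-cell
fields with overlapping ring territories. Results on real images depend on
segmentation quality in ways the clean synthetic cell boundary does not
probe.

## Numerical and interface conventions

- Coordinates are 0-based row-major; contour indices are 1-based with 0
  reserved for the mask interior and −1 for pixels beyond the outermost
  contour.
- Distance bands use half-open intervals (k−1, k] in exact pixel units.
- Ring groups are 4 whole contours; a trailing partial group is dropped.
- Histogram pooling is elementwise summation under shared bin edges;
  measured counts are integers, while exact model evaluations (noiseless
  fixtures) may carry floats.
- The photon gate is inclusive (≥ threshold is valid).
- Masks touching the image border are allowed with a warning; rings are
  truncated where undefined.
- All file writes are atomic (temp file + rename); the native container
  round-trips counts and bin edges bit-exactly. ICS support targets the
  published 1.0/2.0 layout keywords (order/sizes/representation/scale);
  vendor dialects vary and only the written subset is guaranteed.
- Every CLI run logs the config hash and seed; one seed drives all
  randomness in a run.

## Problem sizes

The test suite and the acceptance script run simulations at deliberately
moderate scale, chosen as the smallest sizes at which each property is
sharply resolved: 100 seeds × 3 lifetimes at the 10⁴-photon gate for
estimator recovery, 40 replicates per decade for the 1/√N scaling
exponent, single 130×130 scenes (≈10⁵ photons per ring bin) for end-to-end
gradient recovery, and 500/100 replicates for the null/power calibration
of the slope comparison.

## Known limitations

- Mono-exponential only: no bi-exponential or phasor analysis, no global
  fitting across pixels, no photobleaching correction.
- No IRF handling; data whose rising edge matters need deconvolution
  elsewhere first.
- The unweighted fit's precision degrades for lifetimes long relative to
  the repetition window (τ ≳ T/4); prefer the default weighting there.
- Single cell per field; overlapping ring territories from neighbouring
  cells are out of scope.
- SEC/mass calculators implement the stated arithmetic; they do not pick
  chromatogram peaks or deconvolve spectra.
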