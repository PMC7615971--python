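# flimfret

Quantitative FLIM/FRET analysis of matrix-metalloproteinase (MMP) sensor
hydrogels.

Synthetic PEG hydrogels can carry a genetically encoded FRET sensor — a
donor fluorophore (SFGFP) tethered to an acceptor (mRFP) through an
MMP-cleavable peptide. While the sensor is intact, energy transfer quenches
the donor and shortens its fluorescence lifetime; when cell-derived MMPs
cleave the peptide, quenching is lost and the donor lifetime recovers.
Time-correlated single photon counting (TCSPC) therefore turns MMP activity
into a concentration-independent lifetime readout, both in bulk and within
micrometre-scale rings around individual encapsulated cells.

`flimfret` implements that analysis end to end for anyone working with
TCSPC FLIM data of such sensors:

- **Decay fitting** — per-bin photon arrival histograms fitted with the
  mono-exponential model `f(t) = Z + A·exp(−t/τ)` by Levenberg–Marquardt,
  in a statsmodels-style `MonoExpDecayModel` / `MonoExpDecayResults` pair
  (model-based Poisson weighting by default, plain least squares
  available).
- **Lifetime maps** — 35×35-pixel spatial binning, an inclusive
  10,000-photon gate per bin, per-bin fits, bulk means and red-long /
  blue-short heatmaps.
- **FRET efficiency** — `E = 1 − τ_DA/τ_D` from donor lifetimes, plus
  acceptor:donor intensity ratios.
- **Peri-cellular ring profiling** — invert/normalise, white top-hat,
  Canny edge detection, primary-contour extraction, propagation of
  1-pixel equidistant contours (exact Euclidean distance banding), binning
  into groups of 4 contours (the ~4.7 px laser spot), pooled decay fits
  per ring bin.
- **Statistics** — unpaired two-tailed t-tests (Student pooled default,
  Welch optional), per-cell lifetime-vs-ring slopes, between-group slope
  comparison (t-test on per-cell slopes, pooled interaction regression as
  an alternative), and time-course convergence against a donor-only
  reference.
- **Assay calculators** — chromophore-corrected masses, PEG–protein
  conjugate mass series, SEC calibration, Beer–Lambert concentrations,
  substrate fold-excess, rheology plateau moduli.
- **Synthetic TCSPC generator** — seeded, ground-truthed decays, cleaved /
  uncleaved mixtures and dark-cell-in-bright-hydrogel scenes (80 MHz,
  12.5 ns window, 256 bins, Poisson statistics), so the whole pipeline is
  testable offline.

I/O covers a native HDF5 container, ICS (Image Cytometry Standard) 1.0
read/write and 2.0 read, TIFF ring labels, CSV tables, PNG heatmaps, and a
YAML-configured `flimfret` command line (`simulate`, `fit`, `rings`,
`compare`, `calc`).

## Worked example

Simulate one sensor (quenched) and one donor-only decay at realistic photon
budgets, fit both, and compute the FRET efficiency:

```python
import flimfret as ff

sensor = ff.simulate_decay_histogram(
    ff.DecaySpec(tau=1.88, n_photons=100_000, background_fraction=0.02, seed=1)
)
donor = ff.simulate_decay_histogram(
    ff.DecaySpec(tau=2.35, n_photons=100_000, background_fraction=0.02, seed=2)
)
fit_sensor = ff.fit_monoexponential(sensor)
fit_donor = ff.fit_monoexponential(donor)
print(fit_sensor.summary())
e = ff.fret_efficiency(fit_sensor.tau, fit_donor.tau)
print(f"tau_DA = {fit_sensor.tau:.3f} ns, tau_D = {fit_donor.tau:.3f} ns")
print(f"E_FRET = {100 * e:.1f}%")
```

```
Mono-exponential decay fit: f(t) = Z + A exp(-t/tau)
----------------------------------------------------
photons (total)         100010
fitted bins                256
weighting              poisson
converged                 True
RSS                      266.1
----------------------------------------------------
param         estimate       std err
Z              8.24572         0.547
A              2562.14          12.8
tau            1.86809        0.0084 ns

tau_DA = 1.868 ns, tau_D = 2.339 ns
E_FRET = 20.1%
```

The fitted lifetimes recover the generating 1.88/2.35 ns within their
standard errors, and the efficiency lands at ~20% — the quenching depth
expected for this donor–acceptor pair.

The same analysis runs from the shell; for a full synthetic scene:

```bash
flimfret --seed 1 simulate scene --tau-slope 0.005 --out scene.h5
flimfret rings scene.h5 --n-contours 40 --group 4 --out-csv rings.csv
flimfret calc corrected-mass 58767.81 --chromophores 2   # -> 58726.27
```

## Documentation

`docs/methods.md` describes the model, estimator, geometry conventions,
synthetic-data assumptions and known limitations in detail.
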