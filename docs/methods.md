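# Methods

This note documents the models, conventions, and numerical choices behind
`lutidose`, and what the synthetic phantom does and does not emulate.

## Nuclear data

Lu-177 decay data ship as a versioned JSON file: half-life 6.647 d
(574 300.8 s), a 25-bin approximation of the allowed-shape beta spectrum
(relativistic Fermi function for the Z = 72 daughter; branches 498.3 keV
79.4%, 385.3 keV 9.0%, 177.0 keV 11.6%; binned mean 134.1 keV), conversion
and Auger electron lines adding ~13.8 keV per decay, and the principal
photons (112.95 keV, 208.37 keV, minor gammas, Hf X-rays). The total mean
electron energy per decay is ~147.9 keV = 2.370e-14 J, which is the physical
anchor of the voxel kernel. Electron CSDA ranges in water (ESTAR-style) and
photon attenuation / energy-absorption coefficients (XCOM-style) are
packaged alongside and interpolated log-log. Energies are keV and times
seconds internally; the single conversion constant is
1 keV = 1.602176634e-16 J.

Different published compilations disagree at the sub-percent level (e.g.
half-life 6.647 vs 6.6443 d, mean beta energy 133.6 vs 134.2 keV); such
discrepancies propagate linearly and are far below the Monte Carlo
comparison tolerances used here.

## Phantom generator

The generator emulates *post-reconstruction* quantitative SPECT only:
ellipsoidal regions with uniform concentration and mono-exponential washout
`A(t) = A_ref·2^((t_ref−t)/Te)` are rasterized by voxel-center membership
(world position of a voxel center is `origin + (index + 0.5)·spacing`;
volumes are `voxel_count·voxel_size³/1000` ml), then optionally degraded by
an isotropic Gaussian PSF of stated FWHM and voxelwise Poisson noise on a
counts scale (`counts_per_bq`, default 1e-3 counts/Bq — a deliberately
generic sensitivity scale) before rescaling to Bq/ml. Default acquisition
times are 1, 4, 24 and 72 h p.i.; default uptake is instantaneous at t = 0
so the ground truth is available in closed form; a linear-rise-to-t1 option
mirrors the uptake triangle of the disintegration formula. A single integer
seed drives one `numpy.random.Generator`; noise fields are drawn time point
by time point in order, so outputs are bit-reproducible.

The default test phantom (40³ voxels of 5.08 mm) carries ~1 MBq in a
~7 ml tumor at 72 h with Te = 30 h inside a slower-clearing warm background
— the order of magnitude of the imaged patients. What the phantom does *not*
emulate: projection-domain physics (attenuation, scatter, collimator
response, reconstruction artifacts), inter-time-point misregistration,
breathing motion, and non-uniform intratumoral uptake. Passing the
noiseless round-trip tests therefore validates the *estimator chain*, not
robustness to reconstruction artifacts in real data.

Ground truth includes, per region: activities at the acquisition times, the
rasterized volume, the analytic disintegration count (same uptake-triangle +
tail convention as the estimator, so truth-vs-estimate comparisons isolate
estimation error), and the implied dose for a given kernel energy.

## VOI stage

The enclosing VOI is a deterministic surrogate for a manual contour: the
26-connected component above 20% of the seed-voxel intensity, dilated by a
stated margin (default examples use 10–15 mm). Separation scans thresholds
upward in steps of 1% of the VOI maximum and accepts the first threshold at
which the component containing the hottest voxel has no voxel 26-adjacent to
the VOI's outer boundary (image-border voxels count as boundary). This is
the smallest threshold honoring the "separates tumor from background"
stopping rule, and it is deterministic and testable. Failure to separate at
any threshold raises `SeparationFailure` — the phantom analogue of a tumor
non-evaluable due to adjacent blood-pool activity.

Background correction follows the displayed equation with the shell between
the enclosing and separated VOIs as the background estimate; negative
corrected activities are clipped to zero with a warning. Spill-in/out is
deliberately not corrected. `V_CT` is an input everywhere (ground truth for
phantoms, the transcribed value for fixtures): CT segmentation is out of
scope. TAC samples use fixed-volume (default 3 ml) hottest-voxel region
growing, drawn independently per time point.

## Kinetics

Ordinary least squares on log-transformed values; `λe` is defined as the
negative slope (so `Te > 0` and the back-extrapolation scales upward).
Points ≤ 0 are excluded with a warning. The fit is unusable — triggering the
trapezoid fallback — when the slope is ≥ 0 (slopes within 1e-12/h of zero are
treated as zero), r² < 0.5, or fewer than 3 positive points remain. The fit
is unweighted and uses concentrations; the absolute scale enters only
through `A4`.

The disintegration integral is `N = A1·(t1/2 + 1/λe)`: the `t1/2` term is a
linear-uptake triangle over `[0, t1]`, and the tail anchors the exponential
at `A1` at `t1` (`N_tail = A1/λe`) — the only reading dimensionally
consistent with `A1` being the activity at the first acquisition. The
unshifted alternative differs by the factor `e^{−λe·t1}` (≈ 2–7% for
clinical Te) and is not used.

The trapezoid fallback adds the same uptake triangle, the trapezoid over the
acquisition window, and an analytic tail with the *physical* decay constant.
Two consequences, both verified against a quadrature oracle: (i) over the
window the trapezoid strictly overestimates the convex exponential, bounded
by the classical `max|f''|·Δt³/12` per-segment error; (ii) the physical-decay
tail matches the closed form only when the effective half-life is close to
the physical 159.5 h — at Te = 40 h the two conventions differ by ~89%,
dominated by `A(t4)·(1/λ_phys − 1/λe)`. The fallback is therefore a
deliberately conservative estimate for fast-clearing regions, appropriate to
its role as a last resort when the exponential fit fails.

## Monte Carlo kernel

Simplified point-source transport in unit-density soft tissue, justified
because Lu-177 beta CSDA ranges (< 1.8 mm) are small against both clinical
voxel sizes (3.9 and 5.08 mm), so the center-voxel energy is dominated by
locally absorbed electron energy:

* electrons ≥ 70 keV travel straight lines of their CSDA range; the energy
  deposited in the source voxel is the emitted energy minus the residual
  energy at the voxel exit (inverse range lookup). Sub-threshold electrons
  deposit at the creation point.
* photons ≥ 1 keV get an exponential free path; if the first interaction
  falls inside the voxel, the locally absorbed fraction `μ_en/μ_tot·E` is
  deposited there (single-interaction approximation), the rest escapes.

Per-line particle counts are Binomial(n, yield); directions are isotropic.
The standard error is estimated from 20 batch means (≈ 0.07% at 10^6
decays). The random stream is independent of the voxel geometry, so kernels
for different voxel sizes computed with the same seed share identical
particle histories: the small E(3.9 mm) < E(5.08 mm) ordering (driven by
photon containment) is then a deterministic geometric effect, not Monte
Carlo noise. No coupled photon–electron transport, no bremsstrahlung, no
cross-voxel dose maps: the kernel scores the source voxel only, and the
summed deposition is bounded by the mean emitted energy by construction.

Doses are `D = N·E/(ρ·V_CT)` for tumors (ρ = 1 g/cm³), `D = N·E/m` for the
stomach wall (default m = 0.15 kg), and `D = N·E/m` or `D = N·S` for generic
organs. The kernel path for kidneys/marrow is a local-deposition MIRD
surrogate: absolute organ doses from vendor workflows or blood-based marrow
methods are not reproduced — only the downstream statistics on the packaged
per-patient values.

## Stability quantification

Chromatograms are linear-baseline corrected between trace endpoints, peaks
detected with a 2%-of-maximum prominence floor, and peak regions bounded by
the valleys between adjacent apexes. Percent intact is the trapezoid area of
the peak whose apex lies within the intact retention-time window (default
± 0.5 min) over the total area; degraded species are treated as bulk
non-intact signal rather than identified metabolites. The result is
invariant to uniform count rescaling.

## Summary and test conventions

Median = midpoint (mean of the central pair for even n); IQR = Q3 − Q1 with
inclusive Tukey hinges; reported values are rounded half-up at the printed
precision *only at the report layer*. Reported folds are ratios of medians
rounded at the printed precision (the raw-median fold is also emitted). The
signed-rank test drops zero differences, midranks ties, and computes the
exact two-sided p = 2·min(tail), capped at 1, from the conditional null
distribution of W+ built by dynamic-programming convolution over doubled
midranks (identical to full 2^n enumeration, feasible to n = 25); beyond
that a continuity-corrected normal approximation is used and flagged. No
multiple-testing correction is applied.

Several printed cells in the packaged tables do not reproduce from their own
printed per-patient values under these (or other standard) conventions —
the 5/15/30-min stability medians, some IQRs, the bone-marrow with-arm
median and marrow-dose p-value. The report computes its own values and flags
the mismatches rather than guessing the original software's conventions; the
per-patient fixture files note the typesetting ambiguity of the source
table.

## Problem sizes

Defaults chosen for seconds-scale runs while keeping estimator errors far
below the tolerances being tested: phantoms of 40³ voxels; Monte Carlo
kernels at 2×10^5 decays in unit tests and 10^6 in the headline checks
(s.e. ≈ 0.07%); 500 draws for the Te-recovery simulation, applied at
TAC level (10% multiplicative lognormal noise) since volume-level noise
adds nothing to that property.

## Known limitations

* No projection/reconstruction physics; calibration bias of real
  quantitative SPECT is outside the model.
* Single-interaction photon transport slightly underestimates cross-voxel
  photon dose; irrelevant for the source voxel, wrong tool for organ
  cross-fire.
* The enclosing-VOI surrogate (threshold + dilation) stands in for a manual
  contour; its parameters matter only through the background shell it
  produces.
* Partial-volume voxels are assigned by voxel-center membership; no
  fractional masks.
* Only Lu-177 ships, though the decay-data schema admits other nuclides.
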