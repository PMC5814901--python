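# Methods

This note records the models, algorithms and numerical choices behind the
package, in the order data flows through it.

## Synthetic tightrope movies

The tightrope is treated as a rigid straight segment (taut between beads)
of physical length 16 μm carrying 48.5 kbp, rendered at a configurable
angle (default horizontal). The genomic↔physical map is linear:
s·μm = kbp/48.5 × 16. Each labelled protein in a complex is an isotropic
2D Gaussian point emitter in the channel assigned to it; the whole complex
shares one axial trajectory.

Key parameters (defaults in parentheses):

* **pixel size** (100 nm/px) — not a measured property of any instrument;
  chosen as typical for an EMCCD at 100–160× magnification, and it makes
  the 16 μm tightrope ≈160 px, comfortably resolvable. Configurable.
* **PSF sigma** (1.3 px) — ≈ λ/(2·NA)/2.355 at NA 1.45 for visible
  emission; configurable per run.
* **frame rate** (10 Hz), **movie length** (50 frames) — the acquisition
  convention for steady-state colocalization snapshots (5 s at 10 fps).
* **amplitude** (per species; 105 photons in the SNR-10 experiments) —
  quantum-dot brightness statistics are not published for this assay;
  the SNR-10 convention used throughout the tests is amplitude = 10× the
  background SD, with background 100 photons (shot noise) and 2 ADU
  Gaussian read noise, i.e. SD ≈ √(100+4) ≈ 10.2.
* **dark fraction** (0) — each dot is permanently visible or permanently
  dark for the movie (Bernoulli per dot), reflecting the permanently
  non-fluorescent subpopulation of quantum dots; blinking is modelled
  separately as an optional two-state telegraph and is off by default
  because frame stacking defeats it in the analysis.
* **diffusion** — 1D reflected Brownian motion on [0, L], simulated
  exactly by folding the free path (method of images); damage-bound
  molecules sit immobile at a configured damage coordinate.
* **placement** — uniform along the tightrope; an optional minimum
  pairwise spacing uses the order-statistics spacing transform (sorted
  uniforms on the interval shrunk by (n−1)·d plus the spacings), which is
  exact and never dead-ends, and is applied jointly across all species on
  a tightrope.

The camera model is photon shot noise (Poisson) plus Gaussian read noise.
It deliberately omits EM-gain register statistics, fixed-pattern noise and
3D PSF structure; consequences: localization at a given nominal SNR is
slightly easier than on a real EMCCD, so the ≤0.3 px RMS localization
figure demonstrated on synthetic data is a best case, and passing tests do
not certify performance on real cameras. Polymer dynamics of the DNA are
also omitted (the tightrope never fluctuates transverse to its axis).

## Spot detection and localization

Detection is Laplacian-of-Gaussian at the PSF scale (scale-normalized,
sign-flipped so spots are maxima), candidate maxima thresholded at the
response median + 5 robust SDs (1.4826×MAD), each candidate refined by
least-squares fitting of an isotropic Gaussian + constant offset in a
(6σ+1)² window with an analytic Jacobian, and refined centres closer than
2σ merged keeping the brighter. Coordinates are 0-based pixel-centre.
Thresholding on the LoG response (rather than raw intensity) makes the
detector robust to the flat elevated background of a fluorescent cell
body. On noiseless Gaussians the fit recovers centres to <0.05 px; on
SNR-10 spots the RMS error is ≤0.3 px; on pure-noise frames the false
positive rate is <0.1 per frame at the default threshold.

Channel registration is a least-squares translation from ≥3 matched bead
localizations (split-view colour channels are dominantly offset; an affine
model was judged unnecessary at the accuracy the 3 px colocalization
window requires). The tightrope axis is a total-least-squares line through
spot centres (dominant singular vector), with endpoints at the extreme
projections; orientation is normalized to positive x (then positive y) so
axial coordinates are reproducible.

## Frame stacking

Steady-state snapshots stack the first 50 frames. The maximum projection
is the default (it keeps transiently bound or blinking molecules visible);
the mean projection is used by the end-to-end recovery experiments because
on purely static samples it raises effective SNR by √n frames and makes
the false-spot rate negligible, which an exact-count recovery check needs.
The choice is an explicit argument everywhere.

## Colocalization and census

Two spots from different channels colocalize when their centre distance is
≤3.0 px, inclusive, after registration. Complexes are connected components
of the colocalization graph, so an A–B edge plus a B–C edge implies an ABC
complex even without an A–C edge; a physical trimer's outer members can
exceed the pairwise window, and requiring all pairwise distances would
systematically undercount triples. Components containing two spots of the
same channel are flagged ambiguous and excluded from the census — one
colour per protein cannot resolve them. Complex position is the
intensity-weighted mean of member centres. Census fractions are
100×count/total; the SEM is over per-flow-cell fractions, the flow cell
being the unit of biological replication.

## Damage scoring

Per tightrope, the complex nearest a marker (ties to the brighter) is
tested against the radius. On a hit, that complex alone enters the
statistic and every other complex on the tightrope is excluded from both
numerator and denominator — otherwise stationary non-binders on a
marker-bearing tightrope would dilute the probability. On a miss, all
complexes count as non-colocalized. Tightropes with more than six
complexes (uniform spacing <2.5 μm) are dropped entirely beforehand.

The random-association baseline applies identical scoring against a
virtual marker at L/2 on undamaged tightropes and also reports the
analytic uniform-binding expectation 100×min(2r, L)/L — 3.75% for r = 3 px
(0.3 μm) on a 16 μm tightrope. An observed baseline can exceed 2r/L
whenever binding is non-uniform or the effective capture radius exceeds
the scoring radius; the effective radius is therefore an explicit
parameter and is never fitted silently.

## Tracks, motility, diffusion

Linking is greedy nearest-neighbour per frame (candidates in order of
increasing distance, ties to the brighter spot), with a 5 px jump gate and
a 2-frame gap tolerance; tightropes are sparse after the density filter,
so global assignment would buy nothing. A track is motile when its
positional SD exceeds k× the localization precision (k = 3); tracks
shorter than 10 frames are left unclassified and excluded from fractions.
Under an immobile null with Gaussian localization noise this criterion has
a false-positive rate ≪5%. The SD criterion was chosen over an MSD-slope
test because it remains stable on short tracks and mirrors the visual
"moved together" scoring it replaces.

Diffusion constants come from an OLS fit of MSD(τ) = 2Dτ + offset over the
first quarter of available lags (the offset absorbs localization noise);
displacement pairs are frame-indexed so gaps do not corrupt lags. The
estimator is unbiased but a single 500-step track carries ~60% relative
scatter, so recovery tests average ~150 tracks. A quadratic refit flags
tracks whose MSD is dominated by curvature (directed transport), where the
linear model is invalid.

## Live-cell classification

Cells are segmented by Otsu threshold + connected components + area
filter; border-touching cells are excluded (truncated masks bias
detection). Spots are detected per frame and kept only if they fall inside
the mask eroded by 2 px, because the cell edge produces LoG ridge
responses that otherwise masquerade as persistent spots. A cell is static
iff ≥1 linked track spans ≥90% of frames with ≤2 px positional SD — the
persistence threshold tolerates missed detections and blinking while
excluding diffusers; the number of spots beyond the first does not change
the label. The batch classifier detects once per frame on the full field
and assigns detections to cells, which is algorithmically identical to
per-cell classification but much cheaper.

The synthetic live-cell movies place elliptical (rod-shaped) cells on a
grid with randomized size and orientation; diffuse cells are a uniform
interior (fast diffusion fully motion-blurred), static cells add one
immobile interior spot. Real data additionally show partial blurring,
photobleaching, cell motion and out-of-focus light; the ≥95%
sensitivity/specificity demonstrated here is therefore an upper bound, not
a field calibration.

## Survival statistics

Survival at a dose is the pooled colony concentration (Σcount/Σdilution,
dilution = plated fraction) relative to the matched-replicate unirradiated
control. Replicate fractions are averaged *before* the log transform
(the convention declared for "log relative survival of averaged
survival"); spread is the SD over replicate fractions propagated onto the
log scale, reported as SD rather than SEM for this module only. Plates
with zero treated colonies contribute a limit-of-detection lower bound of
0.5 colonies on the densest plate and flag the result, keeping deep-kill
points finite and plottable. Group comparisons use the two-sided
equal-variance Student's t-test on per-replicate (or per-flow-cell)
fractions.

## Problem sizes in tests and the acceptance script

Recovery experiments use 40 tightropes × 5 complexes (census), 40
single-molecule tightropes (damage), 1000 complexes (dark-dot model),
10⁴–10⁵ molecules (midpoint null), 200 cells × 100 frames (live cell) and
n₀ = 10⁵ colonies (survival). These sizes put 3σ statistical bounds well
inside the effects being checked while keeping the full suite fast; they
are the package's own choices, and all are parameters.

## Known limitations

* No drift correction, no 3D/astigmatic localization, no MLE fitting.
* No binding/unbinding kinetics and no intensity-based stoichiometry.
* No anomalous-diffusion models or HMM segmentation of tracks.
* The camera and cell models are idealized as described above; synthetic
  benchmarks bound what the pipeline can do on real data from above.
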