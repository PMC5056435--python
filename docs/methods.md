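# Methods

## The attenuation model

A dye at height *d* (nm) above the absorbing GO plane emits the fraction

    I/I0 = d^4 / (d^4 + d0^4)

of its free intensity. The form is fixed by two constraints: the
quenching-rate scales as d^-4 for a point emitter coupled to an absorbing
plane, and *d0* is defined as the half-intensity height. The inverse,
d = d0 * (r/(1-r))^(1/4) with r = I/I0, converts intensities to heights;
`relative_depth` is the same inverse with *d0* eliminated through a
measured reference point (a dye on top of a layer of known thickness), so
only relative positions and relative intensities enter.

Calibration solves d0 = t * ((1-r)/r)^(1/4) per reference layer and
averages (unweighted — the references have comparable quoted spreads).
Uncertainty is the larger of the delta-method propagation of the intensity
sds (|dd0/dr| = d0 / (4 r (1-r))) and the empirical spread across
references, both as sds of the mean. With the bilayer (4.1 nm, 48±6%) and
BSA (3.3 nm, 31±6%) references this gives d0 = 4.11 ± 0.19 nm.

The usable axial window is (0.5 d0, 1.7 d0): below it the dye is quenched
into the camera background ("blind region", below ~2 nm for d0 = 4 nm),
above it the curve saturates and intensity noise maps into large height
errors. Components fitted beyond 1.7 d0 are flagged `saturated` and carry
their honestly inflated uncertainties.

## Synthetic study ensembles

The generator emulates the two imaging configurations of the study system:

* **five_state** (bilayer lifted by a protein cushion): heights
  (3.4, 4.2, 5.2, 6.2, 7.5) nm with spreads (0.4, 0.4, 0.4, 0.4, 0.9) nm —
  bottom surface, lower leaflet, centre, upper leaflet, top surface.
  Kinetics are a nearest-neighbour chain at 4 s^-1 per hop (a peptide does
  not skip a leaflet in one jump); this gives uniform equilibrium occupancy
  and dwells of a few video frames.
* **two_state** (bilayer directly on GO): bright states at 3.1 nm
  ("in the pore", 60 ms mean dwell) and 4.0 nm ("at the surface", 260 ms),
  exchanging only through a blind state at 0.8 ± 0.15 nm (250 ms mean
  dwell, re-entry split 50/50). Because the bright states never
  interconvert directly, the composite bright dwell is *exactly* a 50/50
  mixture of 60 ms and 260 ms exponentials — the printed time constants;
  the 50/50 amplitude is a declared convention (amplitudes are not
  printed). The blind state is a stand-in for every sub-detection height
  and is placed deep inside the blind zone so that it is, by construction,
  indistinguishable from background.

State paths are exact Gillespie realisations started from the stationary
distribution. Per frame midpoint the height is drawn as
Normal(position, spread), pushed through the quench law with I0 = 1000
counts, multiplied by (1 + Normal(0, 0.02)) gain noise and offset by
Normal(50, 10) background counts. The printed per-state spreads are treated
as *total observed widths*, so the instrument noise is deliberately small
to avoid double-counting variance. Bleaching is a single permanent
exponential step (no blinking); frames are instantaneous samples (no
motion blur). Traces default to 60 s at 30 fps with a 0.02 s^-1 bleach
rate — the analysed molecule class in this kind of experiment survives
minutes of illumination, and the resulting ~1,200 live frames per trace
(about 46,000 pooled points over the standard 50-trace ensemble) are what
make the five-component model selection well-powered.

Movies render each live molecule as a renormalised 2-D Gaussian PSF
(sigma 1.1 px at 0.16 um/px — diffraction-limited red emission through a
high-NA objective, which is also why a 7x7-pixel aperture captures > 99%
of the flux) on a Poisson background, with per-state lateral diffusion
coefficients increasing toward the membrane surface.

What the generator does **not** emulate: triplet blinking, drift,
non-Gaussian EMCCD excess noise, spot overlap in crowded fields, slow
illumination gradients, and any correlation between axial state and
brightness other than through the quench law. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
noise model, not robustness to every artefact of real recordings.

## State inference

Live (pre-bleach) frames of all traces are pooled; the histogram (uniform
bins) is kept for display while fitting works on the sample.

Two mixture modes:

* **gaussian** — seeded multi-restart Gaussian-mixture MLE
  (scikit-learn EM) on the pooled intensities, BIC over the candidate
  component counts. Appropriate when no quench/noise model is attached and
  for well-separated, mildly curved regions.
* **physical** (pipeline default) — each component's intensity density is
  the *push-forward* of Normal(height, spread) through the quench law,
  convolved with the camera noise (additive background + multiplicative
  gain). Components are parameterised directly in heights. This family is
  the generator's own likelihood, which matters: in intensity space the
  per-state densities are skewed (strongly so near saturation), so plain
  Gaussian components make BIC over-count states, while under the
  correctly specified family BIC behaves. On the five-state twin the plain
  mode selects 7 components; the physical mode selects 5, with N=4 "almost
  as good" — the same near-tie the real data shows.

Numerical notes for the physical mode. The component density is computed by
trapezoid integration over a fixed height grid (0.01 nm step, 0.3 nm to
beyond the 99% intensity point): where the attenuation curve is steep, the
noise kernel is only ~0.1 nm wide in height units, so quadrature placed on
the *component* (e.g. Gauss–Hermite) misses it entirely — the grid must
resolve the kernel. The likelihood is binned (256 bins), which makes EM
cost independent of sample size at negligible approximation error. EM
(closed-form weights, per-component 2-D Nelder–Mead M-steps) runs from
quantile-based seeded starts; because EM crawls on strongly overlapping
components, a bounded full-parameter simplex polish finishes the climb and
is kept only when it improves the likelihood. A blind component — height
capped below the detectability limit, where the density is flat in height —
absorbs the blind-region mass when a background level is supplied; only its
weight is reported. Standard errors of the fitted heights come from the
observed information (numerical Hessian over all free parameters); flat
directions (a barely occupied or saturated component) show up honestly as
large or undefined SEs.

A histogram least-squares mode mirrors the classic visual procedure and is
kept behind a flag; it shares the skewness problem of the gaussian mode.

Per-frame labels are maximum-posterior component assignments; frames below
background + 2 sd are labelled blind (the quench law is never inverted
there — the height is reported as the bound "< 2 nm", not a number); a
3-frame median filter on the combined blind/state sequence suppresses
single-frame flickers in both directions. With the printed spreads,
adjacent states overlap by ~2 sigma in intensity, which caps *any* frame
classifier near the Bayes optimum of ~77% on the five-state twin; the
fitted labels come within a few points of that bound.

## Dwell-time kinetics

Dwells are maximal runs of frames labelled with the chosen state class
(default: the top two components, the surface-proximal pair); runs touching
the trace start, trace end or the bleach frame are right-censored. The
two-exponential mixture

    p(t) = a/tau1 * exp(-t/tau1) + (1-a)/tau2 * exp(-t/tau2)

is fitted by maximum likelihood with multi-start optimisation in
(logit a, log tau1, log tau2). Continuous samples use the plain density;
frame-quantized samples use the interval-censored likelihood
P(k frames) = S((k-1)dt) - S(k dt) — the exact model for durations rounded
up to whole frames. (A continuous density with left-truncation at one frame
must not be used on grid data: a component shrunk below one frame becomes
invisible and tau_fast is unidentifiable along a flat ridge.) A
single-exponential fit (closed form, geometric in the quantized case) and a
likelihood-ratio comparison are always reported; standard errors come from
the numerical observed information.

On 2,000 continuous dwells from the 50/50 60/260 ms mixture the MLE
recovers both constants within two standard errors, with SEs of the same
order as the quoted ±8 and ±30 ms. On frame-quantized dwells at 30 fps the
interval likelihood keeps the fast-constant bias near 5%. Full trace-level
dwell analysis (labels → runs → fit) carries an additional upward bias at
30 fps: blind gaps shorter than one frame merge consecutive dwells and the
median filter removes genuine single-frame visits, so trace-derived
constants overestimate the true ones when the fast time scale is within a
factor ~2 of the frame interval. This is a physics-of-sampling limitation,
not an estimator defect, and is why the headline kinetics are quoted from
dwell samples at the generator's native (continuous) resolution.

## Tracking

Detection: per-frame local maxima above the frame median plus a
threshold (default 5) times the MAD-scaled robust sd; sub-pixel refinement
by intensity centroid of the background-subtracted 7×7 ROI (centroid
rather than Gaussian fitting — the science lives in the integrated
intensity, and the centroid is robust at low SNR). Photometry: ROI sum
minus ROI area times the border-ring median, recomputed every frame so
slow illumination drift cancels. Linking: per frame pair, candidate
(track, spot) links within a maximum displacement are resolved globally in
order of increasing distance, ties favouring the older track; gaps up to 2
frames are bridged; a track that disappears while still bright (last
intensity above half its median) is closed as "bleach", otherwise "lost".
Pixel convention: integer coordinates are pixel centres, origin top-left,
x = column, y = row. On generator movies across 20 seeds the chain
recovers ≥ 95% of molecules with mean position error < 0.3 px and
intensity bias < 3%.

## Problem sizes and determinism

Defaults used by the tests and the acceptance script: 50 traces × 60 s at
30 fps per ensemble (~4.6 × 10^4 pooled live frames), mixture search over
N = 1..7 (five-state) or 1..4 (two-state), 2,000 continuous dwells for the
kinetics fit, 20 seeds × 6 spots × 150 frames for tracker validation.
Every stochastic step takes an explicit seed; the same configuration and
seed reproduce results byte-for-byte.

## Known limitations

* Absolute heights require the calibrated d0 and the unquenched I0; both
  enter multiplicatively, so systematic errors in either shift all
  positions coherently.
* Above ~1.7 d0 positions are reported but weakly identified (flagged);
  the five-state model's top state is in this regime, and its position SE
  is several times larger than the others'.
* Frame-rate limits trace-derived kinetics as described above.
* No hidden-Markov joint inference of states and kinetics: states are
  identified from the marginal intensity distribution, kinetics from the
  labelled dwells. A joint model is a natural extension, deliberately out
  of scope.
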