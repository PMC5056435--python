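# sifa

Analysis toolkit for **surface-induced fluorescence attenuation (SIFA)**:
nanometre-resolution axial tracking of single dye-labelled membrane
peptides in supported lipid bilayers above a graphene-oxide (GO) absorber.

## The problem

A fluorophore near an absorbing plane is quenched with a steep distance
dependence — the point-to-plane analogue of FRET. For a dye at height *d*
(nm) above the GO layer,

```
I / I0 = d^4 / (d^4 + d0^4)
```

where *I0* is the unquenched intensity and *d0* the characteristic
quenching distance at which *I*/*I0* = 1/2 (about 4 nm for UV-tuned GO
monolayers — comparable to a bilayer thickness, which is what makes the
method work). Recording single-molecule intensity traces under TIRF
illumination at 30 frames per second therefore measures *vertical* motion,
while the camera image measures lateral diffusion: the two are decoupled.

Applied to the pore-forming antimicrobial peptide LL-37, this turns
intensity flickering into transitions among discrete transmembrane
positions — surface, upper leaflet, centre, lower leaflet and bottom of the
bilayer — and dwell-time statistics into exchange kinetics.

The package implements the full analysis chain and, because raw recordings
of this kind are not publicly deposited, a seeded synthetic generator
(traces and TIRF movies with ground truth) that stands in for them:

| module | what it does |
| --- | --- |
| `sifa.quench` | d⁻⁴ law, exact inverse, reference-layer conversion, *d0* calibration, sensitivity window (0.5–1.7 *d0*) |
| `sifa.synthetic` | continuous-time Markov state paths, camera-noise traces, PSF movies, dwell samples — all seeded, with ground truth |
| `sifa.tracking` | spot detection (7×7 ROI photometry), greedy nearest-neighbour linking, background-subtracted trace extraction |
| `sifa.states` | pooled intensity PDFs, free-N mixture fitting (plain Gaussian and physically specified modes) with BIC selection, intensity→height conversion, per-frame state labels with blind-region flags |
| `sifa.kinetics` | dwell extraction with censoring, two-exponential MLE (continuous or frame-quantized likelihood), single-exponential comparison |
| `sifa.pipeline` / `sifa.cli` | end-to-end orchestration, JSON configs, `sifa` command-line entry point |

## Worked example

```python
import sifa

# calibrate d0 from the two reference layers (known thicknesses, measured
# relative intensities of a surface-bound dye)
cal = sifa.calibrate_d0([
    sifa.ReferenceLayer("GO-supported bilayer", thickness=4.1, rel_intensity=0.48, rel_intensity_sd=0.06),
    sifa.ReferenceLayer("BSA monolayer",        thickness=3.3, rel_intensity=0.31, rel_intensity_sd=0.06),
])
print(f"d0 = {cal.d0:.2f} +/- {cal.d0_sd:.2f} nm")
# d0 = 4.11 +/- 0.19 nm

# simulate the five-state study ensemble and recover the states
from sifa import states as st
cfg = sifa.RunConfig(seed=1)
traces, truth = sifa.simulate_traces(cfg.state_model(), cfg.quench_model(),
                                     cfg.noise_model(), 50, 60.0, seed=1)
pdf = st.build_intensity_pdf(traces)
fit = st.fit_mixture(pdf, n_range=range(1, 8), seed=1, method="physical",
                     quench=cfg.quench_model(), noise=cfg.noise_model())
print(fit.n, fit.positions_nm.round(2))
# 5 [3.29 4.09 5.21 6.2  7.48]
```

Five components are selected by BIC and their heights recover the
generating positions (3.4, 4.2, 5.2, 6.2, 7.5 nm) within the reported
standard errors; the topmost state sits in the saturation shoulder of the
attenuation curve and is flagged accordingly, with an honestly wider
uncertainty.

The same flow runs from the shell:

```bash
sifa calibrate
sifa simulate-traces --scenario five_state --n-traces 50 --seed 1 --out traces.csv
sifa run-all --seed 1 --out-dir results/run1
```

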