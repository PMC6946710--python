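# psafret

Quantifying homo-FRET — energy transfer between spectrally identical
fluorophores — from changes in fluorescence anisotropy while photoswitchable
fluorescent proteins (e.g. Dronpa) are driven to their off state.

Homo-FRET is invisible to intensity or lifetime measurements, but it
depolarizes emission: a directly excited fluorophore emits with high
anisotropy, while a fluorophore excited through energy transfer emits with
essentially random polarization. As the fluorophores in a cell are
photoswitched off, surviving emitters progressively lose their transfer
partners and the measured anisotropy climbs from its FRET-depressed value to
the transfer-free value. This package turns that climb into a quantitative
readout for protein self-association in live-cell polarization imaging.

## Method

From the background-subtracted parallel and perpendicular channel means of a
region of interest, each frame gives

- anisotropy `r = (I∥ − g·I⊥) / (I∥ + 2g·I⊥)` (g from an isotropic dye
  calibration),
- total fluorescence `F_tot = I∥ + 2g·I⊥`,
- fraction photoswitched `F(t) = (F_tot(t₀) − F_tot(t)) / F_tot(t₀)`.

`r` is regressed on `x = 1 − F(t)` (frames up to 0.8 photoswitched); the
line evaluated at `x = 1` and `x = 0` gives `r_et1` (all fluorophores on,
full homo-FRET) and `r_et0` (complete photoswitching, no FRET). The
anisotropy change `Δr = r_et0 − r_et1` converts to an efficiency-like
quantity,

    drFRET = 6 (r_et0 − r_et1) / (1 + 8 r_et0 − 4 r_et1 + 4 r_et0 r_et1),

the fractional gain of perpendicular-channel signal caused by energy
transfer. Unlike Δr, drFRET is stable across objective lenses and
polarization-mixing conditions, so results transfer between instruments.

High-NA objectives mix the polarization components over their wide
collection cone; the package implements the Axelrod unmixing correction
(`K_a, K_b, K_c` coefficients of the collection half-angle
`θ = arcsin(NA/n)`) both as a forward model in the simulator and as an
optional correction in the analysis.

A physics-based simulator generates dual-view image stacks of photoswitching
oligomers with exact closed-form ground truth (binomial mixture of
Runnels–Scarlata-type cluster anisotropies), so every pipeline stage is
validated end to end against known answers.

## Worked example

```sh
psafret simulate --seed 13 --out demo          # synthetic dimer dataset
psafret analyze --stack demo/stack.tif --rois demo/roi.json --out demo/results
```

The analyze step prints `analyzed 1 ROI(s) -> demo/results/results.csv`; the
CSV holds (values from the run above):

| roi  | r_et1  | r_et0  | delta_r | drfret |
|------|--------|--------|---------|--------|
| cell | 0.2338 | 0.3492 | 0.1154  | 0.2174 |

For this simulated tandem dimer the ground truth (`demo/truth.json`) is
`r_et1 = 0.2333`, `r_et0 = 0.35`, `drFRET = 0.2192`: the pipeline recovers
the anisotropy endpoints to ~0.001 and drFRET to ~0.002. A monomer control
(`n_subunits = 1` in the config) analyzes to drFRET ≈ 0. Grouped results
can be compared with `psafret compare` (Welch t-test or ANOVA +
Tukey–Kramer) and plotted with `psafret report`.

As a library:

```python
import psafret as p

model = p.OligomerModel(n_subunits=2, r_mono=0.35, r_et=0.0, coupling=1.0)
optics = p.OpticsConfig(numerical_aperture=1.4, refractive_index=1.515)
trace, truth = p.simulate_trace(model, p.SwitchingParams(), p.CameraModel(),
                                optics, n_oligomers=10_000, seed=1)
result = p.analyze_trace(trace, optics)
print(result.drfret, truth.drfret_true)   # 0.2187  0.2192
```

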