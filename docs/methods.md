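# Methods

## Physical model

### Photoselection and anisotropy

Polarized excitation preferentially excites fluorophores whose absorption
dipoles align with the field (cos² weighting). For an isotropic population
of immobile fluorophores this bounds the steady-state anisotropy
`r = (I∥ − I⊥)/(I∥ + 2I⊥)` to [−0.2, 0.4]; fluorescent proteins rotate
little within their fluorescence lifetime and sit near the top of that
range. The instrumental bias between the two detection channels is absorbed
into the g-factor, calibrated on a freely rotating dye solution whose true
anisotropy is zero (`estimate_g`). Any residual anisotropy of the reference
dye becomes a systematic offset of g; it is assumed zero, not corrected.

### Cluster anisotropy

For a cluster with `k` on-state fluorophores coupled pairwise with equal
transfer-rate × lifetime product `ωτ`, the steady-state anisotropy used
throughout is

    r(k) = r_mono (1 + ωτ)/(1 + k ωτ) + r_et (k − 1) ωτ/(1 + k ωτ).

The first term is the fraction of emission still carried by the directly
excited fluorophore; the remainder is sensitized emission at anisotropy
`r_et`. This equal-all-pairs-coupling closed form is the package's model
choice for intra-oligomer transfer; geometrically heterogeneous couplings
within one oligomer are not modeled. The coupling maps to chromophore
separation through the Förster radius, `ωτ = (d/R0)⁻⁶`.

Defaults: `r_mono = 0.35` (typical immobile fluorescent-protein anisotropy
in the on state), `r_et = 0` (sensitized emission fully depolarized —
acceptor dipoles randomly oriented relative to the excitation). Both are
configurable; `r_et > 0` models partially oriented oligomers.

### Ensemble mixture and the linearity of psAFRET

With a fraction `p` of fluorophores on, an emitting fluorophore sees a
binomial number of on-partners, giving the intensity-weighted ensemble
anisotropy

    r(p) = Σ_{j=0}^{N−1} C(N−1, j) p^j (1−p)^{N−1−j} r(j+1)

(equal quantum yields and brightness per subunit; off fluorophores neither
absorb nor accept). For a dimer this is exactly affine in `p`, which is why
the anisotropy-vs-fraction-switched data fit a straight line and why linear
extrapolation to the endpoints is exact in that case. For `N ≥ 3` the
mixture is convex in `p`: the curve sags below its chord, i.e. the
anisotropy stays depressed until most fluorophores are off and then rises
steeply. The sag is largest at tight packing (`d ≲ 0.8 R0`) and decays
toward zero as `d/R0` grows — at realistic fluorescent-protein separations
the profile is close to linear, and the package fits the line regardless of
`N`, accepting the small convexity bias for higher-order oligomers as the
method's stated approximation.

### High-NA polarization mixing

A wide collection cone mixes the cartesian emission components into the
channels,

    I∥   = K_c I_z + K_b I_y + K_a I_x
    gI⊥  = K_b I_z + K_c I_y + K_a I_x

with `K_a = (2 − 3cosθ + cos³θ)/3`, `K_b = (1 − 3cosθ + 3cos²θ − cos³θ)/12`,
`K_c = (5 − 3cosθ − cos²θ − cos³θ)/4` and `θ = arcsin(NA/n)`. Assuming
randomly oriented fluorophores (`I_x = I_y`) the system inverts in closed
form; the corrected anisotropy is `(I_z − I_y)/(I_z + 2I_y)`. The same
equations serve as the simulator's forward model, so correction and forward
projection are exact inverses — verified to 1e−10 in the tests. The
`I_x = I_y` assumption is taken as written even under homo-FRET, where
partially oriented sensitized emission could violate it slightly.

Two numerical guards: the unmixing denominator
`D = K_b² + K_aK_b − K_c² − K_aK_c` vanishes as θ → 0, so the correction is
refused when `|D| < 1e−9 · max(K_c², 1)` (analyze uncorrected instead — at
such angles mixing is negligible anyway); and forward mixing with all K
factors below 1e−15 raises a degenerate-optics error. g is applied before
unmixing: the equations operate on `(I∥, gI⊥)` exactly as written. Angles
are degrees at every public interface, radians internally.

A consequence worth noting: the apparent (uncorrected) Δr shrinks
monotonically with the collection half-angle θ — not with NA per se. Across
immersion media the ordering can invert (θ for a 1.0-NA oil lens is smaller
than for a 0.75-NA air lens), while drFRET computed from each condition's
own endpoints stays constant to a few percent. The lens-sweep validation
asserts monotonicity in θ for exactly this reason.

## Estimation pipeline

Per frame: background-subtracted ROI means → `gI⊥` scaling → optional
unmixing → `r`; `F_tot = I∥ + 2gI⊥` (channel domain, also when the
anisotropy is corrected — F(t) is a normalization and needs no unmixing) →
`F(t)` with `F = 0` at the first frame. OLS of `r` on `x = 1 − F(t)` over
frames with `F(t) ≤ cutoff` (default 0.8; data become very noisy beyond
~0.8–0.9 switched) and `F_tot ≥ 5%` of its initial value (low-signal guard,
configurable). `r_et1 = a + b`, `r_et0 = a`, `Δr = −b`; drFRET from the
conversion formula. Errors: `s = √(SSE/(n−2))`, `s_β1 = s/√(SS_xx)`,
`SS_xx = Σx² − (Σx)²/n` — implemented explicitly as the method's standard
diagnostics and checked against an independent OLS implementation.

Endpoints are read from the fitted line, not from raw first/last frames, so
single-frame noise does not propagate into `r_et1`. Negative
background-subtracted intensities are preserved and flagged, never clipped.
Out-of-domain drFRET inputs (denominator ≤ 0, or `r_et0` beyond the
photoselection range) raise; a negative drFRET (anisotropy fell during
switching) is returned with a warning rather than suppressed.

Background is subtracted per frame from a no-signal region, tracking
baseline drift rather than assuming a constant; this choice is logged in
the trace output where both raw and background columns are kept.

## Synthetic data

`simulate_scene` realizes per-oligomer on-state trajectories (independent
Bernoulli off-switching per fluorophore per frame → geometric decay of the
on-fraction; photoswitching is treated as intensity-independent, and
405-nm reactivation cycles are out of scope), computes the exact ensemble
anisotropy and brightness of the realized population, and projects to
channels. `simulate_trace` adds Poisson shot noise, Gaussian read noise and
the camera baseline at trace level; `render_stack` distributes the
expectations uniformly over a polygonal cell region of a 16-bit dual-view
frame (parallel left, perpendicular right, configurable inter-half
translation) and applies the noise per pixel. One integer seed drives all
stochastic draws; identical seeds give byte-identical TIFFs.

Default study conditions: dimer with `ωτ = 1`, `p_off = 0.08` per frame for
50 frames (≈98% switched by the end), 10⁴ oligomers, 200 detected photons
per on-fluorophore per frame, read noise 2 counts, offset 100, gain 1,
64×128 frames with a 33×33-pixel cell region. These give initial per-pixel
signals of a few thousand counts — a bright but realistic live-cell
photoswitching acquisition — and pipeline-recovered drFRET within ±0.02 of
truth across seeds.

What the simulator does not emulate: rotational diffusion during the
lifetime, spectral bleed-through, flat-field inhomogeneity, focus drift,
cell motion, and spatially varying expression. Passing tests therefore
demonstrate correctness of the estimator given the photophysical model, not
robustness to every real-microscope artifact.

## Statistics

Group summaries are mean ± sem. Two groups: two-tailed Welch t-test.
Three or more: one-way ANOVA, then Tukey–Kramer pairwise comparisons with
numerically computed studentized-range quantiles (valid for unequal n;
reduces to classical Tukey HSD at equal n). Cohen's d uses the pooled
standard deviation denominator by default; a compatibility flag divides by
the pooled variance instead, for comparison with reports using that
convention.

## Numerical and design choices

- Polygon ROIs rasterize by pixel-center containment with vertices at pixel
  centers; boundary pixels are included. Membership is computed once and
  shifted rigidly to the second channel, so both channels use identical
  pixel sets.
- Registration of the dual-view halves is integer-pixel: either a
  configured translation or whole-pixel phase correlation on the first
  frame. Sub-pixel registration is out of scope.
- The exponential-with-offset fit of F_tot (`y = a·e^(−bx) + c`) is
  descriptive, seeded from moment estimates; a constant trace is flagged
  degenerate rather than failing. For geometric switching the fitted rate
  approaches `−ln(1 − p_off)`.
- Test and validation problem sizes (10⁴ oligomers, 50 frames, 20 seeds,
  100-point oracle batches) were chosen so the whole suite exercises every
  stage in a few seconds while keeping Monte-Carlo error an order of
  magnitude below the asserted tolerances.

## Known limitations

- drFRET is an efficiency-like index, not a hetero-FRET efficiency;
  converting it to distances or stoichiometries is out of scope.
- The linear fit is exact only for dimers; higher-order oligomers at tight
  packing bias the extrapolated `r_et1` slightly upward.
- The g-factor calibration assumes a perfectly isotropic reference.
- `I_x = I_y` in the unmixing is an approximation under oriented
  sensitized emission.
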