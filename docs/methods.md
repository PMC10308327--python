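# Methods

## The measurement model

A conical nanopipette held at a potential against a reference electrode
passes an ionic current limited by the nanotip region. During nanotip-
localized crystallization the current is a piecewise-structured signal:

1. **Pre-conditioning** (t < 0): a small negative bias (default −0.1 V)
   suppresses uncontrolled mixing; the current is small and negative.
2. **Domain formation**: at time zero the potential switches positive
   (default +1.0 V) and transport of protein and precipitant raises the
   local supersaturation; a viscous, ion-permeable dense liquid domain
   forms at the tip and the current falls by tens of nA within about a
   minute, then relaxes into a gradual drift.
3. **Pre-nucleation (pre-N)**: a noisy plateau. The elevated noise is
   attributed to transient sub-critical assemblies at the tip.
4. **Nucleation** (t_S → t_E): the irreversible formation of one crystal
   produces an abrupt amplitude decrease and a concurrent drop of the
   noise level.
5. **Post-nucleation (post-N)**: a quieter, drifting baseline while the
   crystal grows.

Both nucleation signatures are *relative* changes against the fitted
baselines of the same recording, so baseline drift is absorbed by the
linear segments and no detrending is applied.

## Continuous piecewise-linear regression

All kinetic fits use one primitive: least squares over the continuous
broken-line family

y(x) = β₀ + β₁x + Σⱼ cⱼ·max(0, x − tⱼ),

with breakpoints tⱼ restricted to observed abscissae and at least
`min_segment_points` points per segment. For a fixed placement the model is
linear, so the residual sum of squares is obtained from the 4×4 normal
equations; all Gram entries are suffix sums of 1, x, x², y, xy, precomputed
once as cumulative sums, making each candidate placement O(1). The search is

* **exhaustive** over all admissible placements (≤ 2×10⁶ pairs), which is
  globally optimal over the candidate grid and is what the brute-force
  oracle tests check; ties are broken toward the earliest breakpoint
  (conservative, earlier onset);
* **coarse-to-fine** for longer records: exhaustive on a ~400-point
  decimated candidate grid, then coordinate-wise refinement at full
  resolution within one coarse step, iterated to a fixed point.

Abscissae and ordinates are centred/scaled internally so the normal
equations stay well conditioned for hour-long traces; the final
coefficients and rss are recomputed by `lstsq` on the raw hinge design.

**Model order and significance.** The breakpoint count (0–2) is chosen by
BIC with 2 + 2k parameters (each breakpoint contributes a slope change and
an estimated location). Every retained breakpoint must then pass an F-test
(2 numerator df) against the nested model with that breakpoint removed and
the others held fixed, at α = 10⁻⁴; non-significant breakpoints are dropped
least-significant-first and the smaller model is refitted. The choice of
BIC and of the F-form is a design decision: the data source reports only
the resulting p-value threshold, not the test. On exactly-collinear data
every model order reaches rounding-level rss, so BIC comparisons apply an
rss floor of n·(10⁻¹⁰·range(y))² to avoid rewarding meaningless parameters.

## Nucleation detection

The amplitude channel fits the post-domain current directly. The noise
channel fits the 50-point moving standard deviation (MSTD; 5 s at the
default 10 samples/s), computed with a trailing window and timestamped at
the window end so the channel is causal. Because overlapping windows make
the MSTD autocorrelated over the window length — which would make both BIC
and the F-test sharply anticonservative — the noise channel is fitted on
every 50th MSTD sample (non-overlapping, nearly independent windows),
trading time resolution (5 s, the window itself) for honest significance.
The domain period is excluded beforehand: it ends where the smoothed slope
first recovers above 8% of its steepest (most negative) value.

A channel that resolves two significant breakpoints yields an event
(t_S, t_E, V_N = 1/(t_E − t_S)); the reciprocal-interval rate form follows
the reported rate/interval pairs (1/626.4 s ≈ 1.6×10⁻³ s⁻¹, 1/541.2 s ≈
1.8×10⁻³ s⁻¹), both of which it reproduces. Events are corroborated when
the two channels' intervals overlap; with equal pre/post noise the noise
channel correctly stays silent and the amplitude event stands alone,
uncorroborated. Pre-N and post-N baselines shorter than 8 min trigger a
warning (a soft preference, not an error). Default `min_segment_points` is
2× the MSTD window (100 samples; 2 decimated samples on the noise channel).

## Growth kinetics

Dimensions M and L_A are fitted independently with the same primitive
(≤ max_stages − 1 breakpoints, default two stages). Censored points —
below `detection_limit` pixels (default 2 px of 250 nm, i.e. 0.5 μm) — are
dropped, not imputed, mirroring how lengths are only measurable at or above
the optical limit. Segments with Pearson |r| below `r_min` (default 0.99)
are flagged, not rejected. Face rates are G₁₁₀ = f₁₁₀·(dL_A/dt) and
G₁₀₁ = f₁₀₁·(dM/dt) with configurable geometry factors defaulting to 0.5
(a face advances from the crystal centre at half the dimension's elongation
rate); the exact crystallographic conversion is deferred to the user, and
simulator and estimator share the convention, so recovery results are
convention-independent. The aspect ratio is defined as M / L_A (the
2-pixel/1-pixel resolution floor makes it start near 2); users preferring
the inverse can take the reciprocal.

Frame measurement: threshold (default 0.5), largest connected component,
oriented bounding box via principal axes of the pixel coordinates; when the
two principal variances agree within 5% the orientation is ill-defined and
the axis-aligned box is used. The longer side is M, the shorter L_A.

## Synthetic data: what it emulates, what it does not

The trace simulator adds stage-dependent Gaussian white noise (sd ramping
linearly from the pre-N to the post-N level across [t_S, t_E]) to the
deterministic piecewise template, with optional Poisson-timed Hann-windowed
sinusoid oscillation bursts and an optional exponential EDL charging spike
at the potential switch (both off by default; their magnitudes are free
parameters, as the source reports only their existence). Default study
conditions: 10 samples/s; domain drop 30 nA over 60 s onto a 50 nA plateau
drifting at −0.004 nA/s; t_S = 2809.8 s, t_E = 3436.2 s (the reference
46.83/57.27 min interval); a 10 nA nucleation amplitude step; pre-N/post-N
noise sd 0.4/0.12 nA; 600 s of post-N baseline. The amplitude step and
noise levels are this package's choice of a realistic small-pipette run —
the source gives the phenomenology, not the numbers.

The length-series simulator uses two stages of 5400 s and 9000 s with
per-condition face rates (positive_high: G₁₀₁ 2.3, G₁₁₀ 0.6→1.1 nm/s;
positive_low: 1.5, 0.5→1.1; negative: 0.3→2.2, 0.6→1.5), 60 s frames,
60 nm Gaussian length jitter, floor-quantization to the 250 nm pixel grid
and 2-pixel censoring.

Not emulated: 1/f or other colored current noise, ion-current
rectification and electroosmotic transients, optical diffraction beyond
the pixel floor, non-rectangular (hexagonal-projection) habits, multiple
simultaneous crystals, and evaporation-driven late-time supersaturation
drift. Passing recovery tests therefore demonstrates the estimators are
correct and well-calibrated under white noise and pixel quantization — not
that real recordings meet those assumptions; on instrument data the
significance threshold α and the smoothing option are the practical knobs.

## Numerical and design choices

* Breakpoint candidates are data abscissae; global optimality is over that
  grid, not the continuum.
* Trailing (causal) MSTD anchor; decimated noise-channel fitting (above).
* rss ties break toward the earlier breakpoint.
* Sampling gaps > 2× the nominal interval warn rather than fail.
* Floor quantization of lengths (a crystal spans ⌊L/px⌋ whole pixels);
  zero-noise censoring is therefore monotone.
* Thermodynamic constants come from `scipy.constants` (CODATA);
  activities default to concentrations, the stated approximation, making
  σ = Δμ/(k_B·T) exactly in the tests.
* Problem sizes in the validation studies: 50 replicates per stochastic
  recovery; default traces are ~4150 s at 10 samples/s (~41,600 samples);
  length series are 241 frames. The brute-force oracle suite uses n ≤ 140
  with ≤ 2 breakpoints, where exhaustive enumeration is exact.

## Known limitations

* At most two breakpoints per fit — one nucleation event per trace, two
  growth stages per dimension. Multi-event traces need windowed reruns.
* The F-test assumes independent Gaussian residuals; the decimated noise
  channel approximates this, but strongly colored amplitude noise would
  still inflate significance.
* Coarse-to-fine search on long traces is not guaranteed globally optimal
  (exhaustive search is, and is used whenever the pair count permits).
* The geometry factors are bookkeeping defaults, not a crystallographic
  derivation; absolute face rates inherit their convention.
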