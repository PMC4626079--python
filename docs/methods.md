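# Methods

## Stimulus model

All protocols are defined on a regular grid Δt_stim = 1 ms.  For an
*approach*, x(t) = x₀ − vt and

- angular size Θ(t) = 2·arctan(l / x(t)), in (0, π];
- expansion rate Θ̇(t) = 2lv / (x(t)² + l²), finite everywhere with
  maximum 2v/l at contact.

The grid is truncated at t_c = x₀/v (where x = 0 and Θ = π); the geometry
is undefined for x < 0, so a requested duration beyond t_c truncates and
sets a flag rather than extrapolating.  A *recession* is the exact time
reversal of the corresponding approach; since the reversed size signal
shrinks, the raw reversed Θ̇ would be negative, and the excitatory drive is
defined as the time-mirrored magnitude of the expansion rate (the drive a
motion-energy-like pathway would report).  The
*constant-angular-velocity* protocol grows Θ linearly from θ₀ at a fixed
rate; its parameters are configurable (defaults θ₀ = 0.02 rad,
Θ̇ = 2.75 rad/s over 0.5 s, spanning ~1–80°) because published uses of this
protocol do not state them.

Angles are radians internally; degrees appear only in printed reports.
This convention is forced by the peak-angle law Θ_max = 2·arctan(1/α):
only in radians does α ≈ 4.7 give the empirically sensible ≈ 24°.

**Default geometry.**  The canonical object (half-size 0.06 m, speed
6 m/s) is retained, but the default initial distance is x₀ = 3 m so that
collision falls at t_c = 0.5 s, the time base on which all timing results
in this package are expressed.  Timing-law studies realize each l/v ratio
by scaling the half-size at fixed speed and fixed t_c; the model depends
on the kinematics only through l/v and t_c.

**Lowpass filtering.**  Both optical variables pass through first-order
discrete filters y[k] = ζ·y[k−1] + (1−ζ)·x[k], initialised at the first
raw sample, standing in for the lamina/medulla delay.  ζ = 0 is exactly
the identity (no filtering); the default ζ₀ = ζ₁ = 0.95 gives an
effective lag of ≈ 20 ms at the 1 ms grid.  The filtered signals lag the
raw ones; that lag is the entire source of the approach/recession timing
asymmetry below.

## The η-function and the decoding analysis

η(t) = Θ̇·exp(−αΘ) is evaluated on the raw (unfiltered) optical variables;
the latency δ shifts the evaluation time, implemented by interpolation
with edge values held.  The analytic peak theory — T_rel = α·(l/v) and
Θ(peak) = 2·arctan(1/α), independent of l/v — is exact on the continuous
problem and is verified numerically to within one grid step on a 0.1 ms
grid.

Power-law decodings g_p = (log Θ̇ − αΘ)^p = (log η)^p share η's extremum
times (the common factor in dg_p/dt vanishes where η̇ = 0).  Samples with
Θ̇ < 10⁻¹² are excluded (NaN) rather than clipped, avoiding synthetic −∞
spikes.  For even p the extremum is a minimum of a non-negative series;
`oriented_g_p` converts it via o − g_p with o the trace maximum, and odd p
via g_p − min.  The sigmoid readout S(x) = 1/(1+e^(−ax)) is monotone, so
it preserves extremum locations.  As a control, the partial series
Σ_{p≤35} (log η)^p / p! reproduces η − 1 to 10⁻¹⁰ wherever η ∈ [0.1, 3],
confirming the family {g_p} is information-complete about η.

**Peak-detection RMSE study.**  On a (σ, l/v) grid, i.i.d. Gaussian noise
of amplitude σ is added per sample to the noise-free curve
(t_c = 0.5 s, l = 0.06 m fixed; the ratio realized through the speed);
the global argmax is detected per trial and its RMSE against the
noise-free argmax time taken across trials (default 999; the packaged
test uses 199 to keep runtime small).  g₃ and S(g₃) are affinely rescaled
to η's range before noise is added so a given σ perturbs all curve kinds
comparably.  Flat-peaked curves (g₃, large l/v) are fragile; the sigmoid
restores a sharp peak and beats η overall.

## The membrane model

C_m dV/dt = β(V_rest − V) + g_exc(V_exc − V) + g_inh(V_inh − V), with
g_exc = ϑ̇ and the pooled inhibition g_inh = (γ/N)Σ[ϑ + σξᵢ − Δ₀]⁺.
Defaults: β = 1, C_m = 1, V_rest = 10⁻⁵, V_exc = 1, V_inh = −0.005
(shunting), γ = 500, σ = 0.25, Δ₀ = 0.9, N = 500, ζ₀ = ζ₁ = 0.95.  The
rectified potential [V]⁺ is the firing-rate proxy; there is no spiking
mechanism, no habituation, and no multi-compartment structure.  V(0) =
V_rest (immaterial after the first relaxation block).

**Integration.**  Classical RK4 with dt = 500 μs, plus n_relax = 250
relaxation steps (RK4 with frozen conductances) intercalated at every
1 ms stimulus sample.  For frozen conductances the ODE is linear, so an
RK4 step is exactly the affine map V → V∞ + (V − V∞)·r(z) with
z = dt·(β+g_exc+g_inh)/C_m and r the 4th-order Taylor polynomial of
e^(−z); the relaxation block is applied through r^(n+1), bit-compatible
with looping RK4 but O(1).  Convergence to the equilibrium
V∞ = (V_rest β + V_exc g_exc + V_inh g_inh)/(β + g_exc + g_inh) is
geometric: the residual is below 10⁻¹⁰ of the initial gap whenever
(β+g)·(n_relax)·dt > 25, i.e. for total conductance ≳ 200.  Early in an
approach (total conductance ~1) the per-sample contraction is only ~12 %,
so V genuinely lags V∞ there — this is a property of the scheme, not an
error, and the equilibrium-consistency test applies only where the bound
holds.

**Noise schedule.**  Channel noise is drawn once per run
(`noise_time="frozen"`): every channel keeps its offset ξᵢ for the whole
approach, making g_inh a random but temporally smooth monotone function
of ϑ.  The alternative `"fresh"` redraws all N values each stimulus
sample (white in time).  Both are implemented; frozen is the default
because it reproduces the reference peak statistics (median t_rel
130/79 ms at σ = 0.25/0.50; slopes 1.93 at σ = 0 and 1.10 at σ = 0.75),
whereas per-sample redrawing adds argmax jitter that biases the medians
(121/96 ms; 1.37).  Noise is always frozen during relaxation sub-steps.
An optional excitatory-pathway pool (same mechanism, default off; unit
gain and zero threshold so its mean is the filtered expansion rate)
implements the excitatory-noise variant; enabling it at matched σ leaves
the timing-law slope essentially unchanged.

**Peak statistics.**  The peak is the earliest global maximum of [V]⁺ on
the stimulus grid; t_rel = t_c − t_peak.  Stochastic quantities are
summarized as medians over 20 independent seeds, since the reference
implementation's single fixed seed is unknown.

**Channel-count sensitivity.**  The *mean* pooled input is independent of
N, but its variance scales as 1/N, and because V∞ is convex in g_inh the
pooling variance feeds into the mean response; single-run peak times at
N = 10 can differ from N = 500 by tens of ms at l/v = 30 ms.  The
robustness claim tested here is therefore about the model's predicted
(trial-averaged) response: at the default l/v = 10 ms geometry the peak
of the across-seed mean response differs by ≤ 5 ms between N = 10 and
N = 500.

## Threshold smoothing and the power law

The mean channel response is E[ϑ + σξ − Δ₀]⁺ = μΦ(μ/σ) + σφ(μ/σ)
(μ = ϑ − Δ₀): a linear term, an error function and a Gaussian.  It
reduces to the hard rectifier as σ → 0 and is within 10⁻¹² of linearity
ten noise-SDs above threshold.  The closed form is verified against a
10⁷-draw Monte-Carlo oracle (worked example: level 5, threshold 3,
σ = 3 → 2.4534; a single N = 500 channel average scatters around this
with SE ≈ 0.11).

Power-law characterization uses 13 levels ϑ = 0, 0.5, …, 6 with Δ₀ = 3
and fits a·ϑ^e + c by nonlinear least squares on all grid points — the
offset absorbs the sub-threshold noise floor, without which the σ = 3
curve cannot be matched; the pure two-parameter form and a log-log
regression remain available as options.  Exponents fall with σ
(≈ 2.5 at σ = 1, ≈ 1.7 at σ = 3); the fit degrades toward the hard
rectifier at small σ.

## Timing-law experiments

t_rel is measured across l/v = 5, 10, …, 50 ms (one simulation per ratio,
all sharing the seed) and fitted with iteratively reweighted least
squares using Tukey bisquare weights — identical to OLS on clean linear
data; residual normality is assessed by a one-sample Kolmogorov–Smirnov
test at the 0.05 level.  The slope surface over (σ, Δ₀) shows, at fixed
Δ₀, an interior maximum in σ.  The approach/recession asymmetry is
|t_peak,approach − (T − t_peak,recession)| with the recession peak
mirrored about the stimulus midpoint; it vanishes without filtering and
noise, and is ≈ 41 ms at the defaults (≈ 2× the ~20 ms lowpass lag).

## Fitting framework

The membrane model is fitted through its deterministic equilibrium
response (rectified V∞ with closed-form pooled inhibition), so the
objective is smooth and repeated fits are bit-identical.  Free parameters
are chosen by name (σ, Δ₀, β, γ, ζ₀, ζ₁), bounded
(σ ∈ [0, 5], Δ₀ ∈ [0, 5], β > 0), and optimized by bounded least squares
with 5 starts jittered around the defaults.  Because experimental rates
come in arbitrary units and the default mask carries no amplitude, data
and model are normalized to peak 1 before comparison.  η is fitted as
A·η(t+δ)+o.  The numeric "TR" mask codes used in the source recordings'
captions are kept only as aliases for the explicit name sets.

Spike traces are converted to rates by full-wave rectification, a
first-order lowpass (τ = 5 ms), sub-sampling to 1 ms and Savitzky–Golay
smoothing (51-sample window, order 3); window and order are free
parameters since the original pipeline does not print them.

The synthetic-rate generator produces η-shaped curves, membrane-model
responses on approaches, and constant-angular-velocity responses, with
optional additive Gaussian observation noise; it emulates the smooth
trial-averaged firing-rate estimates of real recordings but none of their
burst structure, habituation, or non-Gaussian variability — passing the
recovery and model-comparison tests therefore demonstrates correctness of
the fitting machinery on in-model data, not fidelity to biological
recordings.

## Numerical and design notes

- Ties at the response maximum resolve to the earliest index.
- Approaches include the contact sample (x = 0, Θ = π, Θ̇ = 2v/l).
- g_p masking threshold 10⁻¹² on Θ̇; masked samples propagate as NaN.
- The logarithmic-compression curve sweeps Θ̇ = 0…50 in steps of 0.1 at
  fixed ϑ (expected pooled inhibition); the log fit excludes Θ̇ ≤ 2.  Fit
  quality peaks (R² ≈ 0.997) when the fixed inhibition is near
  ϑ ≈ 0.65, where the half-saturation conductance sits mid-range of the
  sweep.
- Problem sizes in tests and the acceptance script (20 seeds for medians,
  199 trials for the RMSE grids, 199 repeats for the pooled-input worked
  example) are the package's standard study sizes; all complete in
  seconds on one CPU.

## Known limitations

- No spiking mechanism: all peak statistics are on the rectified
  potential, and phenomena tied to burst timing are out of scope.
- Channels are exchangeable; there is no retinotopy or spatially
  structured input, and no video/pixel stimulus reconstruction.
- The recession drive definition (mirrored magnitude) is one reasonable
  choice; the asymmetry magnitude depends on it.
- Temporal structure of channel noise is not constrained by the available
  description; both the frozen and white-in-time conventions are
  implemented, with measurably different peak statistics (see above).
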