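# Methods

## Model

Tracer kinetics follow the standard two-tissue compartment model with
plasma input AIF(t):

```
dC1/dt = K1·AIF − (k2+k3)·C1 + k4·C2
dC2/dt = k3·C1 − k4·C2
P(t)   = (1−Vb)(C1+C2) + Vb·AIF(t)
```

Units are fixed package-wide: minutes post-injection, rates in 1/min,
activity concentrations in Bq/mL. For irreversible trapping (k4 = 0) the
net influx rate is `Ki = K1·k3/(k2+k3)` and at late times the Patlak plot
`P/AIF` vs `∫AIF/AIF` is linear with slope `Ki` and intercept
`V = Vb + (1−Vb)·K1·k2/(k2+k3)²`.

**Tissue curves are computed analytically**, not with an ODE solver: the
compartmental impulse response is a sum of exponentials, and its
convolution with a sum-of-exponentials AIF (or with the piecewise-linear
interpolant of a sampled AIF) has a closed form. This removes any solver
tolerance from the reference model; the unit tests cross-check it against
an independent stiff ODE solve at `rtol = 1e-10` and agree to ~1e-11
relative. The repeated-eigenvalue case (`(k2+k3+k4)² = 4·k2·k4`, a
measure-zero parameter set) is handled explicitly with `t·e^{−αt}` terms.

## The AIF-free extrapolation fit

Under the well-mixed assumption the late-time AIF is mono-exponential,
`AIF(t) = AIF0·e^{−λ(t−t0)}` with a single global λ. Substituting into
first-order kinetics gives, relative to the first late frame t0,

```
P(t) = P(t0) + α·(1 − e^{−λ(t−t0)}),   α = AIF0·(Ki/λ − V),
P∞   = P(t0) + α = Ki·(iAIF0 + AIF0/λ) = Ki·iAIF∞ .
```

Note the **sign of the V term in α**: writing the vascular/free
contribution with a *positive* sign would make the extrapolated value
`P∞ = Ki·iAIF∞ + 2V·AIF0`, destroying the exact proportionality to Ki.
With the negative sign the relation `P∞ = Ki·iAIF∞` holds identically,
which is also what the phantom experiments in `tests/test_acceptance.py`
verify (voxel-wise ratio `P∞/Ki` constant to CV < 1e-5 on the noiseless
phantom). This package therefore uses the negative-sign form throughout.

Fitting is two-stage:

1. **Global λ** — weighted nonlinear least squares of the three-parameter
   model on a large-ROI TAC, weights `w_j = Δt_j·DF_j` with
   `DF_j = 2^{−mid_j/T½}` (mid-time from injection; T½ defaults to the
   F-18 value 109.77 min). The optimizer is scipy's trust-region
   reflective `least_squares` — a bounded Levenberg–Marquardt analogue;
   bounds on λ (default `[1e-3, 1]` 1/min) are required because α diverges
   as λ→0. 25 log-spaced starts in the bounds guard against local minima
   ("lowest weighted SSE wins; SSE ties break toward smaller λ"). `p0`
   and `α` are re-initialized from the data at each start (first-frame
   value; last − first). The fitter is deterministic; a seed only matters
   if start jitter is explicitly enabled.
2. **Voxel maps** — with λ̂ fixed the model is linear in `(p0, α)`; each
   voxel is a closed-form 2-parameter weighted least-squares solve on the
   design `[1, 1−e^{−λ̂(t−t0)}]`. `t0` is the mid-time of the first late
   frame. Voxels whose mean activity is below `voxel_mask_fraction`
   (default 0.05) of the brightest voxel mean are skipped and flagged
   (air; fraction 0 disables skipping). Negative `P∞` can optionally be
   floored at zero, again flagged.

Classic Patlak uses the same `Δt·DF` weights so the two methods are
compared on equal footing (whether the original regressions were weighted
is not documented; equal treatment is the comparable choice).

`Ki` conversion divides `P∞` by `iAIF0 + AIF0/λ` and therefore requires
a-priori knowledge of the input function (e.g. a population-based AIF);
`SUV∞ = P∞/(dose/weight)` needs only subject metadata.

## Phantom: what it emulates, what it does not

The generator produces a labelled 32×32×8 voxel geometry (air, elliptical
soft-tissue body, two spherical lesions), per-label two-tissue parameters,
a 9 × 5-min frame schedule starting 15 min post-injection (the 15–20 min
window where dephosphorylation is still negligible; total span 45 min),
and a bolus-shaped AIF

```
AIF(t) = 3000·e^{−0.04t} + 20000·e^{−t} − 23000·e^{−4t}   [Bq/mL]
```

which is zero at t = 0, peaks near 12 kBq/mL at ~0.5 min, and whose fast
terms have decayed below 1e-5 relative by 15 min — so the late-time tail
is *exactly* `λ = 0.04`/min exponential, the compliant regime of the
well-mixed assumption. Frame values are duration-weighted averages of the
continuous tissue curve (scanner binning), assigned to the frame mid-time.
With uniform frame durations this averaging maps the extrapolation model
onto itself (only `p0`/`α` shift, λ and `P∞` are unaffected), so it
introduces no bias in the quantities of interest; the Patlak *intercept*
does pick up a few-percent bias from it, which is why V is treated as a
diagnostic only.

Default rate constants (background `K1=0.10, k2=0.63, k3=0.07` → Ki=0.01;
lesions `0.16/0.45/0.15` → 0.04 and `0.12/0.50/0.10` → 0.02 /min) sit in
the published FDG/FLT head-and-neck range and were chosen with the
equilibration time constant `1/(k2+k3) ≤ 1.7 min`, so the compartmental
transient has decayed to < 0.05% of signal by the 15-min acquisition
start: the default phantom satisfies the late-time linear-regime premise
*by construction* (slower k2 values leak a percent-level transient into
the first frame and visibly bias λ̂ — a real effect users should expect
with early t0 and slow kinetics, reproducible by customizing
`PhantomSpec`).

Noise is zero-mean Gaussian with SD `σ·sqrt(max(v,1 Bq/mL)/(Δt_j·DF_j))`
— a count-statistics surrogate for decay-corrected OSEM data at late
times, when the biodistribution changes slowly. It is spatially
independent: no reconstruction correlations, no attenuation/scatter, no
partial-volume blur (an optional Gaussian PSF flag exists, default off).
A green phantom test therefore establishes correctness of the estimators
under the model's own assumptions, not robustness to reconstruction
artifacts.

## Numerical choices

- λ bounds `[1e-3, 1]` 1/min; 25 log-spaced multi-starts; `ftol = xtol =
  gtol = 1e-10`.
- Degenerate voxels (zero signal, rank-deficient design) yield zeros plus
  a flag, never an exception; a λ̂ that makes the voxel design degenerate
  raises.
- Sampled AIFs are linearly interpolated and never extrapolated;
  infinite-time integrals are only defined for parametric AIFs.
- The noise-variance floor is 1 Bq/mL, preventing zero-variance frames in
  air.
- The paired t-test uses the explicit `t = mean(d)/(sd(d)/√n)` formula
  with the two-tailed p from the regularized incomplete beta function;
  zero-variance differences raise rather than returning NaN.
- NIfTI maps are float32; uncompressed `.nii` output is byte-deterministic
  for identical inputs.

## Known limitations

- A voxel-wise or regionally varying λ (violating the global well-mixed
  assumption) is out of scope; so are reversible-uptake (k4 > 0) Patlak
  generalizations, denoising, and multi-bed-position stitching.
- Ki conversion is only as good as the supplied tail prior (`iAIF0`,
  `AIF0`, λ); no population AIF library ships with the package.
- The packaged TB-ratio table is fixture data for the cross-method
  statistics; the underlying patient images are not available, so those
  statistics are the only patient-scale quantities the package can
  reproduce.
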