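# Methods

## The problem

Integrated reflection intensities from 3D electron diffraction (3D ED /
MicroED) come with counting-statistics uncertainties that strongly
underestimate the real scatter of symmetry-equivalent measurements: the
dominant deviations arise from dynamical diffraction, radiation damage and
instrumental instability, not from Poisson noise. Kinematical refinement
weights reflections by 1/σ², so mis-stated e.s.u.'s (estimated standard
uncertainties) directly damage the refined structure. This package
calibrates per-measurement e.s.u.'s against the internal evidence of the
dataset itself — the spread of symmetry-equivalent intensities — and
provides the surrounding machinery (hkl I/O, Laue-group merging, merging
statistics, a pixel-noise model, and a synthetic-data generator with known
ground truth).

## Error models

With `I_hl` the *l*-th measurement of unique reflection **h** and `σ_hl` its
counting e.s.u.:

* **model 0** — no adjustment: the propagated integration variance is used
  as is.
* **model 1** — the common e.s.u. of all members of a group with
  multiplicity n ≥ 2 is the Bessel-corrected sample standard deviation
  `s_h`. Reflections measured once take the mean e.s.u. of comparable
  reflections from a lookup table with ten equal-count intensity bins and
  0.2 Å⁻¹ resolution bins (nearest non-empty resolution bin in the same
  intensity bin as fallback, then the global mean). The equal-count binning
  assigns the remainder N mod 10 one per bin from the strongest bin down.
* **models 2 and 3** — the SDFAC/SDB/SDADD three-parameter inflation

      σ'_hl = s_fac · sqrt(σ_hl² + s_B·max(I_ref, 0) + (s_add·I_ref)²)

  with `I_ref = ⟨I⟩_h` (inclusive group mean, model 2) or `I_ref = I_max,h`
  (largest equivalent intensity, model 3). The two models differ **only**
  in the reference fed to the σ' formula; the normalized deviations are
  always taken from the mean,

      δ_hl = (I_hl − ⟨I⟩_h) / σ'_hl .

  A mean-referenced deviation is essential: deviations from the group
  maximum would be non-positive by construction and could never be normal.
  Model 3's point is that referencing σ' to `I_max` assigns large e.s.u.'s
  to high-variation groups without inflating the global parameters, which
  keeps strong, clearly visible reflections "observed" (I > 3σ).
  Negative reference intensities (possible after background subtraction)
  contribute nothing to the linear term, keeping the variance positive.

Under the inclusive-mean convention a reflection measured once has δ = 0,
and both members of an unequal n = 2 pair under model 1 have |δ| = 1/√2
exactly — the constant steps at ±0.707 that low-redundancy datasets show in
their normal probability plots.

## Calibration by normal-plot linearization

If the e.s.u.'s are correct the δ_hl are standard normal, so the sorted
deltas plotted against the theoretical quantiles `q_i = Φ⁻¹((i − ½)/N)`
fall on the identity line (the `(i − ½)/N` plotting position is the
default; `i/(N+1)` is available). The parameters are fitted by minimizing

    D = Σ_i (δ_(i) − q_i)²

over (s_fac, s_B, s_add), with singletons excluded from the plot.

Numerical design, where choices were genuinely open:

* **Re-sorting.** The textbook procedure alternates "minimize D with the
  order frozen" and "re-sort" supercycles. A frozen permutation suffers
  regression attenuation — the optimal uniform scale shrinks the deltas
  toward the delta/quantile correlation, and the alternation relaxes only
  geometrically (hundreds of cycles). The objective therefore re-sorts the
  deltas at every evaluation; the quantiles stay fixed. The outer supercycle
  loop is retained and declares convergence when the ordering is stable, the
  relative change of D is below `tol` (10⁻⁸) or the parameters move by less
  than `param_tol` (10⁻⁶); it typically terminates after 2 cycles.
* **Optimizer.** Nelder–Mead on (log s_fac, √(s_B/β), √(s_add/α)), where α
  and β are data-derived scales that make the three directions comparable;
  the square transform enforces s_B, s_add ≥ 0 and log keeps s_fac > 0.
  Default start is the identity (1, 0, 0); convergence from it is robust.
* **Degeneracy.** D is a distribution-level statistic. When the counting
  variance is itself nearly linear in intensity (σ₀² ≈ gain·I + const), the
  s_fac and s_B directions are close to collinear and D has a long, flat
  valley: the fitted triple is then determined far more precisely as a
  variance *field* σ'(I) than as individual parameters. Datasets whose
  counting sigmas vary independently of intensity (different frame
  backgrounds) identify the parameters much better. This matters when
  interpreting fitted parameter values, and it shaped the synthetic
  validation conditions below.

## Outlier rejection

Tukey's quartile fences on the deltas: values outside
[Q1 − k·IQR, Q3 + k·IQR] are flagged, with quartiles by linear interpolation
(the common "type 7" rule) and k = 1.5 by default (fences at ±2.70σ for
normal data, expected false-flag rate 0.70%). In an n = 2 group a flagged
member drags its partner with it. The first pass runs on the uncorrected
data; then fit (outliers excluded, group statistics recomputed over the
survivors) and re-flag (all measurements, e.s.u.'s corrected with the
current parameters) alternate until the parameters are stable and the
outlier count stops changing.

One subtlety: after rejection, the surviving deltas are an interior-censored
sample. Fitting them against quantiles for the reduced sample size stretches
the fit (the empirical extremes stop at the fence, the quantiles do not),
which inflates the flag rate and biases s_fac downward; giving every
rejected point an extreme rank squeezes the fit when contamination is heavy.
The survivors therefore keep interior ranks of the full sample, with the
per-side allowance capped at the expected normal fence-tail fraction
`Φ(−(0.6745 + 1.349k))` — rejected points beyond that allowance are treated
as contamination carrying no rank. With this rule the clean-data flag rate
matches normal theory (0.70% measured at k = 1.5) and parameter recovery
under 5% gross contamination is unbiased.

**Known limitation.** Under heavy contamination the model-3 fit can exploit
its own reference: a gross outlier often *is* the group maximum, so
inflating the intensity-proportional terms hands contaminated groups large
σ' and quietly suppresses them, dragging the parameters far from truth
(observed: s_fac ≈ 0.73 at truth 1.1 with 5% outliers at 20× inflation).
Model 2's mean reference is far less exploitable and recovers parameters to
within a few percent under the same contamination. In practice outlier
fractions are well below 5% and rejection is iterated, but a model-3
calibration of visibly contaminated data deserves a model-2 cross-check.

## Merging and statistics

Unweighted group mean as the merged intensity; merged e.s.u.
`sqrt(Σσ'²)/n` propagated from the corrected e.s.u.'s (optionally floored
by the scatter-based standard error `s_h/√n`); observed flag `I > t·σ` with
t = 3 by default. `R_int = 100·ΣΣ|I_hl − ⟨I⟩_h| / ΣΣ I_hl` over groups with
n ≥ 2. R factors follow the conventional pairing — R(obs) on |F| over
observed reflections, wR(all) on F² over all, GOF with N − N_par degrees of
freedom — with weights `w = 1/(σ²(F_o²) + (u·F_o²)²)` and instability
factor u = 0.01 by default. Merged intensities never depend on the error
model; only sigmas and observed counts do.

## Pixel-noise model and integration variance

Pixel variance `var(c) = γ·G·c + ψ` (gain G, cascade factor γ ≥ 1
inflating the Poisson term, dark-image pixel variance ψ), propagated over a
peak region S with rim-estimated background:

    I = Σ_S c_i − n_S·b̄,   Var(I) = Σ_S var(c_i) + (n_S/n_rim)²·Σ_rim var(c_j).

The generative process used to validate this by Monte Carlo is a compound
Poisson signal — electron count ~ Poisson, per-electron gain fluctuation
with variance γ − 1, scaled by G — plus Gaussian dark noise of variance ψ;
its variance is exactly γ·G·E[c] + ψ. Agreement is verified to better than
2% relative at 10⁵ draws for three parameter settings.

## Synthetic data: what it emulates and what it does not

The generator draws true intensities from the acentric Wilson (exponential)
law, multiplicities from a configurable distribution whose default mirrors
low-redundancy 3D ED practice (30% n = 1, 25% n = 2), resolutions uniform
in d*, and Gaussian measurement errors whose true standard deviation
follows the three-parameter model at known (s_fac, s_B, s_add). The stored
sigma is the *uncorrected* counting value `sqrt(gain·max(I,0) + b²)`, with
the background floor b drawn per reflection from 45·(1 ± 0.6) counts —
frame-to-frame background variation, which is also what makes s_fac
statistically separable from s_B (see the degeneracy note above). A
configurable fraction of measurements has its error draw inflated by a
factor (20 by default), preserving sign symmetry.

The `consistency` switch controls what the errors are referenced to:
`"true"` adds independent noise to the true intensity (realistic; deviations
from the realized inclusive mean then carry the factor (n−1)/n);
`"mean"`/`"max"` center and rescale the within-group draws so that the
deviation of each member from the realized group reference is exactly
N(0, σ'²) — the idealized regimes in which the model-2 and model-3
estimators are exactly consistent, used for parameter-recovery validation.
For `"max"` the error scale solves the per-group fixed point
s = σ'(max of realized members).

Default study conditions (chosen once, on the identifiability analysis
above, and for physical plausibility): Wilson scale 400 counts, truth
(1.1, 1.0, 0.05) — the mild-correction regime of well-processed data, with
s_fac near 1, s_B near 0 and s_add small. Recovery validation runs at
uniform multiplicity n = 12 (5000 groups, 60 000 measurements), where the
inclusive-mean convention is unbiased; across seeds both models recover
s_fac to better than 7% and s_add within 0.015. The model-2/model-3
comparison runs on max-consistent data with 35% singletons and strong
proportional errors (s_add = 0.18): there model 3 keeps decisively more
reflections observed (the singleton mechanism: both models reference a
singleton's own intensity, so model 3's smaller fitted parameters directly
preserve its observed flag), and the fitted model-3 parameters lie
elementwise at or below model 2's as a trend over replicate datasets. Per
single dataset the elementwise comparison can flip in the s_B coordinate —
a direct consequence of the valley degeneracy, not of the models.

What the generator does **not** emulate: resolution-dependent error
structure, correlated (frame-wise) systematic errors, non-Gaussian
dynamical-diffraction deviations, per-frame scale factors, and partial
recording. Passing tests therefore demonstrate the calibration machinery's
correctness and its behaviour under the stated statistical assumptions, not
the full phenomenology of experimental 3D ED data.

## Degenerate inputs and tie-breaks

σ ≤ 0 records are rejected at parse time with a report. A group whose
members are all identical has sample_std = 0; model 1 assigns it unchanged
and the deviation computation then refuses the zero e.s.u. explicitly.
Groups reduced to one member by outlier rejection leave the plot. Fewer
than four deltas make Tukey fences meaningless: a warning, no flags.
Quartile ties break toward the lower resolution bin in the lookup-table
fallback. All randomness flows through one seeded generator; equal seeds
give byte-identical datasets and calibration results.
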