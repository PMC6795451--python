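# Methods

## Models

**Total drug.** An IV bolus into a two-compartment system gives a serum
concentration that is a sum of two decaying exponentials,
`C(t) = A·e^(−αt) + B·e^(−βt)` (A, B in µg/mL; α, β in 1/day; t in days).
The dose and micro-rate constants are deliberately not represented
separately: the hybrid intercepts and rates are what concentration data
identify, and everything downstream needs only them. All four parameters
are strictly positive; C(0) = A + B is the full bolus and C is strictly
decreasing to zero. No ordering of α and β is imposed — the model is
symmetric in its two terms and fitted data can put the fast phase in
either slot — but `canonicalized()` reports α ≥ β for human-readable
output.

**Modification kinetics.** An increasing PTM (Asn deamidation,
N-terminal pyroglutamate) follows pseudo-first-order conversion of the
unmodified pool: `P(t) = 1 − (1 − P0)·e^(−kt)`, with the modified
*fraction* P0 ∈ [0, 1] at dosing and rate k ≥ 0 per day. Internally every
level is a fraction and every rate a fraction per day; percent-scale I/O
is converted at the boundary. This convention is strict because rates for
these reactions are conventionally quoted on the percent scale
("0.5394% per day" = 0.005394/day), an invitation to a 100× error.
Decreasing attributes (Met-oxidation fluctuation, high-mannose clearance,
C-terminal lysine loss) do not follow this law and are out of scope.

**Variant exposure.** The concentration of the modified sub-population is
the product `C_pqa(t) = C(t)·P(t)`; the subject exposure to the variant
over a window is its AUC. Expanding the product gives exponentials only,
so the AUC has the closed form

```
∫ C·P = ∫ C − (1−P0)·[ A/(α+k)·(e^(−(α+k)t0) − e^(−(α+k)t1))
                     + B/(β+k)·(e^(−(β+k)t0) − e^(−(β+k)t1)) ].
```

Closed form is the default AUC method. A sampled-grid trapezoid mode is
also provided because exposures in study reports are conventionally
computed on the collection time points; on a convex decay curve the
sparse-grid trapezoid overestimates the exact integral by ~1.5% over
56 days, and both conventions must be reproducible. Which mode a reported
number came from is therefore an explicit choice, not a guess.

**Repeated dosing.** With linear kinetics, identical doses every τ days
superpose: the trough before dose m sums the m−1 circulating doses at ages
τ…(m−1)τ, and the peak adds the fresh bolus A + B. Each aged dose has been
modifying since it was given, so the variant trough weights each dose by
its own modified fraction, Σ P(iτ)·C(iτ), and the observable modified
level at a trough/peak is the variant-to-total ratio. "Pre-dose" is the
left limit at the dose instant (new dose excluded); "post-dose" adds the
bolus instantaneously. The geometric-series limits give closed-form
steady states for the concentrations and for the PTM levels; the
steady-state pre-dose level is

```
P_ss,pre = [A·(g(α) − (1−P0)·g(α+k)) + B·(g(β) − (1−P0)·g(β+k))]
           / [A·g(α) + B·g(β)],        g(r) = 1/(e^(rτ) − 1),
```

and the post-dose form adds P0·(A+B) to the numerator and A+B to the
denominator. These closed forms are verified against brute-force series
summation (vectorized, early exit when a term falls below 1e-14 of the
partial sum, cap 10^5 terms, non-convergence raised) to ≤1e-10 relative
over 1000 randomized parameter draws in the test suite.

A regimen-level exposure shortcut is provided for trough/peak-only
sampling designs: the first interval is integrated exactly and every
later interval is approximated by a straight line from its peak to the
next trough. Windows shorter than one interval fall back to the plain
single-dose integral.

## Fitting

Both fits minimize untransformed-scale least squares with
`scipy.optimize.least_squares` and report R² on raw concentrations/levels
(R² ≥ 0.95 is flagged as a good fit in reports, below as poor).

*Biexponential*: optimized over (log A, log B, log α, log β) so positivity
holds by construction with an unconstrained optimizer. Initialization is
classical curve peeling — log-linear fit of the terminal phase (last ≥3
points) for the slow term, then the positive residual for the fast term —
which is deterministic, so fits are reproducible without random restarts.
The requirement that back-extrapolated C(0) exceed the first post-dose
measurement enters as a penalty residual active only when violated, since
it is an inequality on A + B, not a box bound. Standard errors come from
the Gauss–Newton curvature at the optimum, delta-method-transformed back
to the natural scale. Effectively mono-exponential data (rates collapsed
within 1e-6 relative, or one intercept below 1e-6 of the other) is
returned with a `degenerate` flag and `converged=False` rather than an
exception. At exactly α = β the model evaluates continuously to
(A+B)·e^(−αt), so no special-cased limit form is needed. Each
concentration profile is fitted on its own; a study arm with several
animals is summarized by fitting the mean profile.

*First-order PTM*: bounded trust-region fit of (P0, k) with P0 ∈ [0, 1],
k ≥ 0; P0 is estimated jointly with k rather than pinned to the pre-dose
measurement, so its uncertainty is reported too. An all-equal series
returns (P0 = level, k = 0) with an explanatory message; its R² is NaN
(undefined at zero variance).

Both estimators follow the scikit-learn API (`fit`/`predict`/
`get_params`; fitted attributes with trailing underscores) and are
clonable, so they compose with sklearn model-selection tooling.

## Peak-area reduction

Site-level percent modified is 100·modified/(modified+native) EIC peak
area; records with both areas zero are not quantifiable and propagate NaN
(never silently 0). Ionization-efficiency differences between the modified
and native peptide are not corrected by default; a per-site response
factor (default 1.0) can be supplied where a correction has been
characterized. Chromatographic integration itself is upstream of this
package. Capture-recovery QC is the eluate-to-input ratio of
marker-normalized drug peak areas; ≥ 99.5% is the pass threshold for
unbiased capture.

## Synthetic studies

The generator emulates the two reference designs: a single IV dose sampled
at {0, 5 min, 4 h, 12 h, 1, 3, 7, 14, 18, 30, 42, 56 d}, and a biweekly
5-dose regimen with a dense first interval (post-dose, 1 h, 4 h, 1, 3,
7 d) plus trough/peak pairs at each later dose. Noise is multiplicative
lognormal on concentrations (constant CV, defaulting to 5% — typical
ELISA precision) and additive Gaussian in percentage points on PTM levels
(default SD 0.3 pp, typical LC-MS peptide-map repeatability), truncated to
[0, 100]. Concentration and PTM noise use independent child streams of
one master seed: identical seeds give byte-identical tables, and changing
one noise source never perturbs the other. Trough samples are generated
from the left-limit model value, peaks from the right limit. Default
generating parameters are the reference (fitted) parameter sets, so
synthetic experiments exercise the realistic regime.

What the generator does *not* emulate — and hence what passing recovery
tests do not demonstrate about real data: inter-animal PK variability,
target-mediated (nonlinear) disposition that bends accumulation beyond
~72 days, immunogenicity-driven clearance changes, below-quantitation
censoring, and assay-specific correlated errors. The parameter-recovery
experiment (default 100 replicates at the default noise; ~20 s on one
CPU) reports bias, RMSE, and median absolute relative error per
parameter, with the fitted fast/slow roles aligned to the truth before
comparison.

## Known inconsistencies in the reference values

The reference multiple-dose parameter set reproduces published trough/peak
predictions only approximately: direct superposition from the printed
(rounded) parameters gives a dose-5 trough of 66.6 µg/mL and a
steady-state trough of 73.9 µg/mL with steady-state Asn-site-2 levels of
16.1%/8.2% (pre/post), where the original analysis — evidently carried
through on unrounded internal parameters — reports 70.6, 81.4, and
17.9%/9.7%. The gap is systematic (~5–10%) and not recoverable from the
printed precision, so these values are documented here as consistency
notes; the package treats the printed parameters as given rather than
"correcting" them. Similarly, the printed single-dose total AUC matches
the sampled-grid trapezoid convention while the printed variant AUCs match
closed-form integration: both modes are provided, and the reported
exposure fractions are consistent with the closed-form total.

One published steady-state formula contains a typographical slip (its
B-term reuses the α exponential where the series derivation requires β);
the implementation uses the internally consistent form, which the series
oracle confirms.

## Numerical choices

- Times are days everywhere; sub-day sampling times are fractional days.
- Exposure fractions print at one decimal in percent; JSON carries full
  precision.
- `doses_to_steady_state` declares convergence when trough and peak (and,
  when a PTM is supplied, both levels) sit within a relative tolerance
  (default 1%) of their steady states.
- Steady-state accumulation terms with rate·τ > 700 are set to zero
  (the exponential would overflow; the true term is below 1e-300).
- Acceptance-style checks run at the study's own problem sizes (12-point
  sampling grid, 56-day window, 100 recovery replicates, 1000 randomized
  oracle draws), which keeps the full suite within a few seconds.
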