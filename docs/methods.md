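# Methods

## Measurement model

A patient breathes through a valve system into a reservoir; exhaled air is
pumped (flow rate `Q` of 1 or 4 l/min) through a tube (volume
`V_tube ≈ 20 ml`) and a particle/progeny filter into the measurement
chamber of a flow-through ionization-chamber radon monitor operated in
one-minute cycles. Two readings are recorded 3–5 min apart once the signal
is stable. The chain from instrument reading `R` (kBq/m³) to exhaled
Rn-219 concentration `a` (kBq/l) is

    a = f_cal · R / 1000 · exp(λ · V_tube / Q)

with calibration factor `f_cal = 2.3` (valid for readings in
600–2000 kBq/m³) and decay constant `λ = ln 2 / T½`. Background is
negligible (orders of magnitude below the readings) and omitted by
default; a per-session offset hook exists in the session model if ever
needed.

Censoring is two-sided and structural, not statistical: above
2000 kBq/m³ the display saturates to "> 2000" (right-censored at the
exhaled equivalent, 4.85 kBq/l at 4 l/min or 5.68 kBq/l at 1 l/min);
below 600 kBq/m³ the instrument switches signal-processing regime and no
calibrated conversion exists (left-censored at 1.45 / 1.70 kBq/l). Censor
status travels as an explicit field (`point` / `greater_than` /
`less_than`), never encoded in the number.

### Half-life and tabulated decay factors

The nominal Rn-219 half-life is 3.98 s, giving decay-correction factors
1.0536 (0.3 s transit) and 1.2323 (1.2 s). The campaign table tabulates
1.054 and 1.234; the latter back-computes to T½ ≈ 3.96 s. The package
default is 3.98 s (configurable), but when a campaign row carries a
tabulated factor the pipeline uses it verbatim, so the shipped table is
reproduced exactly and the half-life question is isolated from the
statistics. Similarly, the shipped table's early-time-point bounds for
administrations 1–3 (4.61 / 4.82 alongside factor 1.054) are inconsistent
with the 4.85 bound elsewhere; they are stored as printed and not
reconciled.

## Pairing rules

Each session's two recordings combine into one final result:

| pair | result |
|---|---|
| point + point | point at the arithmetic mean |
| greater-than + greater-than (equal bounds) | greater-than at the bound |
| greater-than + greater-than (unequal) | greater-than at the smaller bound, with a warning (weaker statement; case never observed) |
| point + greater-than | greater-than at the lower of the two values |
| less-than + less-than | less-than at the bound (larger bound if unequal, with warning) |
| point + less-than, outlier-flagged | the point value (failure discarded) |
| point + less-than, unflagged | refused (`UnresolvedCombinationError`) |

The one observed point/less-than pair was judged a sampling failure
(aspiration of ambient air) by the original investigators; the package
encodes that as an explicit per-recording flag in the data rather than an
automatic rule, because a silent heuristic would manufacture statistics.
An opt-in `auto_outlier` mode applies the same discard with a warning —
the synthetic-data pipeline uses it, since the generator labels its own
failures.

One tabulated final (administration 2, late) is not the mean of its two
recordings (4.61, 4.82 → printed 4.82). The table stores the printed
value; the pipeline recombines from the recordings (4.715). The effect on
the late geometric mean is ≈ 0.1%.

## Censored-lognormal estimation (regression on order statistics)

With 75% (early) and 35% (late) of finals right-censored, the package
estimates lognormal parameters by q-q regression:

1. **Ranking.** Measured entries — points, plus less-than entries at
   their bounds — are sorted ascending into ranks `1..k`; right-censored
   entries occupy ranks `k+1..n` ordered by bound (stable ties). Their
   true values exceed bounds near the top of the sample, so top ranks are
   the natural placement; where exactly among themselves they sit only
   matters for imputation, not for the fit.
2. **Plotting positions.** Default Hazen, `pᵢ = (i − ½)/n`;
   Weibull `i/(n+1)` and Blom `(i − 3/8)/(n + ¼)` are selectable. The
   original spreadsheet convention is undocumented; Hazen was chosen
   because it reproduces the published late-time-point GSD (1.67) and R²
   (0.98) essentially exactly and the GM within 1%, and it was fixed
   before being applied to anything else.
3. **Fit.** OLS of `ln(value)` on `Φ⁻¹(pᵢ)` over the measured entries
   only; right-censored entries are excluded. The less-than entry enters
   at its bound (conservative: it keeps the left tail represented and
   matches how the measured-data count of 11 was reported); a
   `strict_less_than` mode drops it. A negative fitted slope warns rather
   than errors — statistics stay well defined on adversarial input.
4. **Imputation.** Each right-censored entry is imputed as
   `exp(μ̂ + σ̂ · Φ⁻¹(pᵢ))` at its own rank. An imputation below its
   censoring bound is logically inconsistent with the bound and triggers
   a warning (it is kept, not clipped — clipping would bias the mean).
5. **Summaries.** GM = exp(mean log of measured + imputed);
   GSD = `exp(σ̂)` (distributional) or the sample log-SD of
   measured + imputed (empirical); 95th percentile =
   `exp(μ̂ + 1.645 σ̂)` or the empirical 95th percentile.

The published 95th percentiles (8.11 and 11.52 kBq/l) correspond to
z ≈ 1.88, which matches neither `z = 1.645` nor empirical interpolation;
the discrepancy is documented, both modes are provided, and no attempt is
made to chase the printed numbers.

Plain statistics of the uncensored subset (median / range) are reported
alongside, as a censoring-free anchor.

**Degenerate inputs.** Fewer than 3 results, or fewer than 3 measured
entries, raise `InsufficientDataError`; zero quantile variance raises
`DegenerateFitError`; all-equal values give slope 0 and constant
imputations.

## Pharmacokinetic cross-checks

Exhaled Rn-219 tracks Ra-223 blood concentration (no tissue accumulation
is possible at a 4 s half-life), so blood-clearance factors from the
pharmacokinetics literature scale concentrations between time points.
Factors are configuration data with citations: ≈ 3 between 20–30 min and
3–4 h (read off published clearance diagrams, hence a generous ±50%
margin on its band), 22.5 between 1 min and 4 h, and an alternative
4.1–5.5 band from published PK parameters. Verdicts are reported, never
enforced: the measured early/late ratio (~1.9) falling below 4.1–5.5 is
itself the finding (heavy early censoring biases the early GM low).

## Synthetic-data generator

`simulate_campaign` inverts the measurement model: true concentration
drawn lognormal(GM, GSD) → divided by the flow rate's decay factor and
the calibration factor → two recordings with independent multiplicative
lognormal noise → range censoring → occasional below-evaluability
sampling failures, which the generator places in recording slot 2 with
the outlier flag set (the generator knows its own failures, as the
original investigators identified theirs).

Defaults are the study conditions: GM 4.4 kBq/l, GSD 1.67 (late time
point), flow rates 1 and 4 l/min in equal shares (8 vs 9 administrations
in the campaign), paired-recording noise GSD 1.05 (campaign pairs differ
by ~5–15%), failure probability 0.05 per recording (3 of 66 campaign
recordings), applied activity ≈ N(4.4, 0.7) MBq clipped at 2 MBq
(weight-based dosing range). One seeded `numpy` generator drives
everything; the seed is recorded in the truth table.

Not emulated: within-session signal drift, correlated noise between the
paired recordings, instrument background, physiological time structure.
Recovery results therefore validate the estimator under the assumed
lognormal/multiplicative-noise model, not against instrument systematics.

Validation sizes (chosen as standard Monte-Carlo practice for this kind
of estimator): censoring-fraction check at n = 10⁵ against the
closed-form normal tail (±3 binomial SE); parameter recovery with 100
replicates of n = 200 sessions (|GM bias| < 5% observed ≈ 0.7%);
consistency check of RMSE over n ∈ {50, 200, 800} with 30 replicates
each; ROS-vs-censored-MLE agreement within 10% at n = 200 (observed
≈ 0.2%). The censored MLE (direct Nelder–Mead optimisation of the
censored lognormal likelihood) exists only as an independent test oracle,
not as a production estimator.

## Known limitations

* The early time point has only 4 measured values; its fitted GM/GSD are
  convention-sensitive (alternative plotting positions move the GM by a
  few percent) and should be read as indicative.
* Extreme values above the range limit are unobservable in principle;
  the imputed tail inherits the lognormal assumption entirely.
* The clearance factors are read off published diagrams; no compartmental
  PK model is fitted.
* Instrument behaviour below 600 kBq/m³ is uncharacterised; less-than
  bounds are handled as hard limits.
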