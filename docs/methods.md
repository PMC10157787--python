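# Methods

This note records the models implemented by `aeroscope`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Oxygen uptake from closed-phase slopes

Within each closed (flush-off) window the dissolved-O2 decline is fit by
ordinary least squares of O2 on time (per second internally, reported per
minute, because loggers sample in seconds while rates are conventionally
per minute). The mass-specific uptake is

    MO2 = |slope| · (v_R − v_F) / m,

v_R the respirometer volume (L), v_F the fish's displacement volume
(L; equal to its mass under the 1 kg = 1 L assumption) and m the mass (kg).

Visual screening of regressions is replaced by three programmatic flags:

- `negative`: slope < 0 (an O2 increase cannot be uptake; such windows are
  invalidated rather than converted),
- `linear`: r² at or above a configurable threshold (0.9 for MMR windows,
  0.85 for overnight validation),
- `artifact_free`: no single-point residual jump larger than 5 residual
  SDs (default multiple; catches probe spikes while tolerating smooth
  curvature).

Cycle windows come from an explicit phase column when present, otherwise
from a flush/measure schedule, otherwise from auto-detection of sustained
O2 rises. Final truncated windows shorter than 60% of the nominal closed
duration are discarded; slopes on very short fragments are unstable. The
first post-chase window is a special shorter closed period (cycle 0)
starting the moment the chamber seals.

Background microbial respiration can be subtracted (linearly interpolated
between pre- and post-trial rates, passed through the same volume term)
but defaults to off: background measured around trials of large fish in
frequently flushed chambers is negligible.

## Per-fish metabolic phenotype

- **Chase MMR** (after 1 h and after 18 h of thermal exposure): the
  steepest OLS slope with r² > 0.9 over any window of ≥ 90 s within
  cycle 0, searching all start positions in 1-s increments *and* all
  window lengths. The search space must be explicit for "steepest" to be
  well defined; tests pin the implementation to a brute-force enumeration
  of every (start, length) pair. The search does not extend past cycle 0.
- **Overall MMR**: maximum of both chase estimates and every validated
  overnight MO2, computed only for fish with more than 60 overnight
  values (a sparse record cannot support a credible maximum).
- **RMR**: the 0.10 quantile of validated overnight MO2 (r² > 0.85,
  at least 60 values), using numpy's linear interpolation between order
  statistics. The alternative reading — the mean of the lowest decile —
  is available via `method="decile_mean"`.
- **Aerobic scope**: AAS = MMR_overall − RMR, FAS = MMR_overall / RMR for
  survivors; both are set to 0 for fish that died during the trial,
  regardless of any rates measured before death — a dead fish has no
  scope, and dropping mortalities would overstate a population's capacity
  at lethal temperatures. A survivor whose RMR reaches its MMR is computed
  as-is but flagged.
- **Mass adjustment**: mass-specific rates are referred to a 3.5 kg fish
  via rate·(m/3.5)^(1−b), with b = 0.58 for MMR and 0.67 for RMR.
  Group FAS is the mean of individual ratios, not the ratio of group
  means. Scaling exponents can be re-estimated from whole-animal rates by
  log10–log10 least squares with optional per-group intercepts; a
  mixed-model version is deliberately out of scope (single-level synthetic
  data cannot identify random effects).
- **Q10** between treatment means: (R_X/R_12)^(10/(T_X−T_12)).

## Recovery and EPOC

%AAS(t) = 100·(MMR_overall − MO2(t))/AAS uses the overall maximum as its
reference, while %MMR(t) = 100·MO2(t)/MMR_chase uses the stage's own chase
maximum. Because the chase maximum is often below the overall maximum,
%AAS at time 0 generally starts above 0%. Measurements are assigned to
10-min blocks (0–50 min) by their window midpoint — unbiased when cycle
lengths vary — and averaged within block. recMMR50 is the time of the
first measurement falling within 48–52% of the chase MMR; records that
jump across that band are excluded with a reason rather than interpolated.

EPOC fits a cubic smoothing spline to the overnight (t, MO2) record, with
the penalty chosen by generalized cross-validation (override via `lam`),
then integrates max(spline − RMR, 0) on a 0.1-min grid from the chase
until the spline first drops to RMR·(1+tol), tol = 2% — exact equality
never occurs on noisy data. Records not reaching that level by the 300-min
horizon are flagged incomplete; records with ≤ 60 points are ineligible.
The stop rule truncates a mono-exponential tail by tol·RMR/k, about 0.7%
of the closed-form total (MMR−RMR)/k at the default simulator parameters;
tests account for this known bias. Hourly blocks 1–5 partition the same
integral and sum to the cumulative value.

## Thermal performance curves

Per-fish AAS against test temperature is fit by least-squares quadratic,
with mortalities entered as zero scope (the headline analysis; a
survivors-only view is available and can flatten the apparent decline at
lethal temperatures). For a concave fit, closed forms give
Topt = −c1/(2c2), AAS_max = AAS(Topt) and
T_pejus_upper = Topt + sqrt((1−θ)·AAS_max/(−c2)) at threshold θ = 0.80.
Peak diagnostics are reported only when c2 < 0 and the vertex lies within
the observed temperature range ± 3 °C — an extrapolated vertex is
meaningless. Uncertainty is the SD of Topt/T_pejus over a bootstrap that
resamples fish (default 500 draws); degenerate resamples (convex fit,
fewer than three temperature levels, out-of-range vertex) are dropped and
counted. Functional warming tolerance is the maximum environmental
temperature minus T_pejus_upper, and may be negative.

## Survival

P(survive|T) = 1/(1+exp(b·(ln T − ln M50))), binomial likelihood over
per-temperature counts, maximised by Nelder-Mead from a grid of starts in
(ln M50, ln b). The ln-temperature parameterisation is the standard
two-parameter dose-response form and is scale-stable. The 95% CI on M50
inverts the profile deviance at the χ²(1) cutoff (Wald available as an
option; profile is preferred because group counts are small and intervals
asymmetric). All-survive, all-die and completely separated outcomes return
a boundary flag with missing CI instead of a spurious estimate. The
population likelihood-ratio test compares a pooled curve against
per-population curves with df equal to the number of extra parameters
(2 per additional curve).

## Synthetic-data generator

The generator emulates an acute thermal-challenge study on adult salmon:
two populations × four test temperatures (12, 18, 21, 24 °C), 54.5 or
98 L chambers, 15-min cycles (9 min flush + 6 min closed; a 5-min sealed
window right after each chase), ~18 h of overnight recording after the
first chase and ~1 h after the second, Gaussian probe noise (default
0.02 mg L⁻¹) with optional linear drift, and Bernoulli survival under the
same log-logistic law the estimator fits (defaults M50 = 21 °C /
slope 25 for the coastal population, 23.6 °C / 14 for the interior one).

Recovery kinetics are mono-exponential: MO2(t) = RMR(T) +
(MMR − RMR(T))·e^(−kt), RMR(T) = rmr12·Q10^((T−12)/10), chosen as the
simplest model with a closed-form oxygen debt (MMR−RMR)/k for oracle
tests. Spontaneous overnight activity is modelled as rectangular MO2
excursions with a small per-cycle probability (default 0.006, starting
after hour 2) whose height can exceed the chase MMR — this is how the
overall maximum can exceed the post-chase maximum, and tests can force it
deterministically. Phenotype draws give masses ~1.4–7.2 kg, rmr12 around
2.4 mg O2 kg⁻¹ min⁻¹, Q10 around 1.7, MMR around 11.3, k around
0.05 min⁻¹, sex-dependent organ masses and hematocrit around 55% with a
small fraction of low-hematocrit fish to exercise the eligibility filter.
Within-individual MO2 variance is not reported for studies of this kind,
so the noise default is a choice, not an estimate.

One deliberate idealisation: within each closed window the simulated MO2
is held constant at its value when the chamber seals (zero-order hold).
Real uptake varies within a window; the hold makes the generative model
exactly invertible by OLS slope fitting, so the ledger carries a
well-defined per-cycle truth and noise-free round-trip tests can demand
agreement to 1e−6. Mortalities die at a uniform random time overnight,
truncating their trace. The generator does not model chamber mixing
dynamics, solubility corrections (O2 is already in mg L⁻¹), multi-fish
chambers or diurnal RMR cycles — so passing tests demonstrate correctness
of the estimators under the stated generative model, not robustness to
every artifact of real optode data.

## Problem sizes and determinism

All randomness flows from explicit seeds (`numpy.random.default_rng`);
pipeline stages derive their seeds from the single run seed, and the same
config and seed reproduce byte-identical tables. Test and verification
sizes were chosen to keep the default suite around a minute: brute-force
sliding-window oracles on 100 fixtures of 150 s at 1 Hz, the exhaustive
survival grid oracle (b ∈ [0.1, 100], M50 ∈ [10, 30], 0.01 steps) on a
handful of fixtures, 100-seed M50 recovery at n = 500 per temperature,
and noise-free end-to-end runs on two fish at 0.5 Hz.

## Known limitations

- The quadratic is the only TPC family; skewed thermal performance is not
  representable (by design — it is the analysis being reproduced).
- Bootstrap SDs for Topt/T_pejus are a declared stand-in for an unstated
  published uncertainty procedure; exact reproduction of printed ± values
  is not claimed.
- Profile CIs on M50 can hit the scan span on flat likelihoods (returned
  as missing on that side rather than extrapolated).
- The LRT's df counts added parameters; published df conventions vary.
- Temperature is the only dose in the survival model; no time-to-event
  structure.
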