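# Methods

This note documents the models, estimators and numerical conventions
implemented in `magnospike`, the choices made where the design was
genuinely open, and what the synthetic-data tests do and do not
establish about real recordings.

## Data model and conventions

Spike trains are ordered arrival times in seconds (strictly ascending,
within a stated record duration); the deposited-data resolution of
0.1 ms is carried as metadata and input times are never rounded.
Interspike intervals (ISIs) are reported in milliseconds, the unit in
which all patterning statistics are quoted. Every bin and window is
half-open, `[a, b)`, including window membership for rate and response
calculations — this guarantees that contiguous bins partition the record
with no double counting (the count-conservation property is tested). An
ISI lying exactly on a bin edge therefore belongs to the right-hand bin.
Record duration comes from the sidecar metadata when present, otherwise
from the last spike time.

Dispersion statistics use the sample (n−1) denominator throughout,
matching the spreadsheet built-ins (`SKEW`, `KURT`) whose bias-corrected
conventions the skewness and excess-kurtosis formulas reproduce:

    skew = n/((n−1)(n−2)) · Σ z³
    kurt = n(n+1)/((n−1)(n−2)(n−3)) · Σ z⁴ − 3(n−1)²/((n−2)(n−3))

with z standardized by the sample SD. Both are verified against an
independent implementation to 1e−10.

## ISI statistics

The CV is sample SD / mean of the ISIs: 1 for a Poisson process,
below 1 for regular firing, above 1 for clustered or phasic firing. The
ISI histogram uses 1-ms bins by default; the mode is the centre of the
maximal-count bin, declared undefined when the maximal count falls below
`mode_min_peak_count` (default 5) — the operational reading of a cell
firing too slowly to register a clear mode — and ties break toward the
shorter interval. Across-cell averages use distributions normalized to
unit mass, zero-padded to a common length, with unweighted per-bin mean
and SD.

One caution established during testing: at realistic sample sizes
(~50,000 ISIs) the argmax of a broad unimodal 1-ms histogram jitters by
roughly ±10 ms between realizations. The analysis default remains 1 ms
(it is the convention the statistics are defined on), but generator
property tests that need a stable mode estimate read it from a 5-ms
histogram.

## Hazard function

Post-spike excitability is estimated per 10-ms bin as

    hazard[t, t+10) = 100 · (#ISIs in [t, t+10)) / (#ISIs > t+10 ms)

The denominator is implemented exactly as written — intervals strictly
greater than the bin's **right** edge — even though the textbook discrete
hazard uses the count at risk at the left edge (`#ISIs ≥ t`). A
`conventional=True` variant exposes the textbook form; it is never the
default. The two differ appreciably only where a bin contains a large
fraction of the surviving intervals. Computation stops at the first bin
with a zero denominator (`valid_up_to`).

The summary takes the maximum over bins whose right edge is ≤90 ms (peak
and its position, reflecting the peak of post-spike depolarization), the
asymptote as the unweighted mean of the fifteen bins [140,150) …
[280,290) ms, and the **peak hazard** as max − asymptote, an index of the
depolarizing afterpotential (DAP) amplitude. Summaries are flagged
undefined when the hazard is not valid through 290 ms. Under an
exponential ISI law the estimator is flat at 100·(e^{λw}−1) per bin,
which supplies a closed-form oracle; on arbitrary ISI lists it is checked
exactly against brute-force counting.

For the population view, cells are grouped into 10-ms bins of peak time
and the per-bin mean ± SD of peak hazard is reported per animal group;
single-cell bins report SD = 0 with n = 1 so downstream consumers can
flag them.

## Burst segmentation

A burst is a period of ≥5 s containing ≥20 spikes separated by ISIs
≤1 s, with >5 s between bursts. The two printed criteria interact:
chaining by ISI ≤1 s can leave gaps of 1–5 s between qualifying chains,
which would violate the >5 s interburst requirement. Segmentation
therefore proceeds: (i) chain spikes with consecutive ISIs ≤1 s;
(ii) chains with span ≥5 s and ≥20 spikes become candidates;
(iii) candidates separated by ≤5 s merge, the gap (and any stray spikes
in it) absorbed into the burst span; (iv) the remaining interburst gaps
are silences, all >5 s by construction. This merge rule is the only
reading under which both criteria hold simultaneously; it is recorded in
output metadata. Burst span is measured first-spike-to-last-spike.

Statistics (mean burst duration, mean interburst duration, pooled
intraburst rate Σspikes/Σduration, spikes per burst) use **complete**
bursts only — those bounded by at least the minimum silence of
burst-free record on both sides — mirroring the restriction to complete
bursts and complete interburst intervals; records with no complete burst
raise an error recommending a longer recording.

The phasic classifier requires ≥10 min of record, ≥2 bursts with
intraburst rate above 4 spikes/s, and ≥1 interburst silence that is
*near-silent* (rate below `silence_rate_threshold`, default
0.5 spikes/s). The last condition is essential: an irregular continuous
train produces burst-shaped ISI chains, but its interburst gaps still
contain spikes at the background rate, whereas genuine phasic silences
are nearly spike-free. All thresholds live in `AnalysisConfig`.

## Stimulus-response quantification

CCK and phenylephrine responses compare the 5 min after injection with
the 5 min immediately before (the protocol records ≥10 min of stable
basal activity but quantifies against "basal rate" without a stated
span; 5 min mirrors the response span and is configurable). Both delta
(spikes/s) and percent-of-basal are reported; percent is undefined
(None) at zero basal. Basal and response windows never overlap, and the
delta is antisymmetric under exchanging the two segments (tested).

Cell classification from the CCK response: phasic cells are vasopressin
cells regardless of delta; otherwise delta > +0.3 spikes/s → oxytocin,
delta < −0.3 → continuous vasopressin, |delta| ≤ 0.3 → unresponsive
(undetermined identity).

The hypertonic-infusion quantifier takes the stimulus onset as pump-on
plus a 5-min infusion-line lag, requires ≥10 min of pre-pump record, and
measures basal over the 5 min before onset (10 min for phasic cells,
whose burst cycle needs the longer window). The 30-s-binned rate series
is expressed as change from basal. The headline response is the mean
rate 20–30 min after onset minus basal. The osmoresponsiveness slope is
a least-squares fit through the origin of the mean change in 5-min bins
against mmol NaCl infused at the bin midpoints, with the standard
schedule 2 mol/L × 26 µL/min (1.56 mmol by 30 min); for a ramp that is
linear in time the midpoint evaluation makes the fit unbiased.

The hypovolaemia (PEG) response is the rate 30–45 min post-injection
minus a 10-min basal. Peristimulus-time histograms accumulate counts in
40-ms bins over a 2-s post-window (configurable) across ≥10 stimuli and
express them as a percentage of the mean pre-stimulation count per bin
over a 1-s pre-window; the pre/post spans are not dictated by any
protocol constant and are logged with each run.

## Spike-triggered averaging

Averages are built on a fixed grid (default −20 to +100 ms at the native
0.1-ms sampling; the post-spike afterpotential of interest lasts
30–80 ms) from all spikes whose window lies inside the trace.
Normalization then (1) re-references the grid to the maximum negative
deflection t₀, (2) subtracts the baseline measured over [−15, −10) ms
(i.e. 10–15 ms before the spike), (3) divides by the (negative) trough
value, which simultaneously scales the spike height to 1 at t₀ and flips
the record positive-going — recorded extracellular spikes are
negative-going; presentation convention is depolarizing-up. The
operation is deterministic, scale-invariant, and guarded against double
application. Baselining is applied to the final average rather than per
spike; for a linear mean the two are identical.

The clean-spike filter keeps spikes not followed by another spike within
100 ms (the last spike is always kept); when the minimum ISI exceeds the
averaging window the clean-spike and all-spike averages agree to
numerical precision, the synthetic analogue of the empirical observation
that the two are indistinguishable. Population waveforms are unweighted
across-cell means ± SD of normalized averages on the overlapping grid.

## The renewal spike generator

The generator is a discrete-time renewal model: synaptic input arrives
randomly at `input_rate` (events/s) and the firing intensity at elapsed
time Δt since the last spike is

    λ(Δt) = input_rate · exp(−H·e^{−Δt/τ_H} + D·e^{−Δt/τ_D})

zero within an absolute refractory period; in each 0.1-ms step a spike
occurs with probability 1−e^{−λ·dt}. H and τ_H describe the
hyperpolarizing afterpotential (HAP) — amplitude dimensionless (log
units of rate suppression), time constant in ms — and D, τ_D the slower
depolarizing afterpotential. With H = D = 0 the model is homogeneous
Poisson (ISI CV = 1); H > 0 produces relative refractoriness, a positive
ISI mode and CV < 1; D > 0 lifts the hazard above its asymptote. This
exponential-modulation form is the minimal model consistent with random
input gated by exponentially decaying afterpotentials; it is not a
conductance-based neuron model and has no plateau/dynorphin mechanism
for phasic bursting.

*Sampling.* Because the ISIs of a stationary renewal process are iid,
trains are generated by exact inversion: the per-step cumulative hazard
is tabulated on the 0.1-ms grid over the refractory period plus ten
afterpotential time constants, a standard-exponential draw is inverted
by binary search, and the constant-intensity tail beyond the grid is
sampled geometrically. This reproduces the discrete-time law exactly
while vectorising over intervals (50,000 ISIs in ~50 ms). The analytic
mean rate — 1/(dt·Σₖ Sₖ) from the same tabulated survival — serves both
as the oracle for the mean-rate fidelity test (simulated rate within 2%)
and for `calibrate_input_rate`, which root-finds the input rate that
yields a requested output rate.

*Time-varying experiments* (CCK transients, infusion ramps) break the
iid structure, so they use exact Ogata thinning against the envelope
max(rate)·e^D. Scripted effects are expressed as additive changes in
output rate and converted to an input-rate multiplier via the analytic
base rate; for a Poisson base this conversion is exact, under strong
afterpotentials it is first-order. The CCK-like transient is an alpha
profile x·e^{1−x} (x = t/peak time) with default peak at 2.5 min,
decaying below 5% of peak by 15 min; the infusion ramp applies
slope × mmol(t) with the 2 M × 26 µL/min schedule and the 5-min line
lag.

*Phasic generator.* Bursts and silences alternate with truncated-normal
durations; within bursts spikes follow the intraburst renewal model
calibrated to the requested rate, and silences are spike-free. Defaults
emulate the salt-loaded phenotype: mean burst 79 s (SD 53), mean silence
24 s (SD 15), intraburst 8.1 spikes/s. Two numerical choices matter.
First, the truncation floor is 6 s — just above the segmentation
criteria — because an untruncated normal silence distribution with these
moments puts ~10% of its mass below 5 s, which would merge adjacent
bursts and bias every recovered statistic; the quoted SDs are
between-cell spreads of per-cell means, so the within-cell floor does
not misrepresent them. Second, the underlying location parameter is
adjusted (root-finding on the truncated-normal mean) so the *truncated*
mean equals the requested mean, keeping the generated conditions on
target rather than shifted upward by truncation. The generator can
return its realized burst/silence intervals, and recovery tests compare
segmentation output against that realized truth — so they test the
estimator, not the duration sampler.

*Voltage synthesis* overlap-adds a spike template (negative gaussian
deflection, post-spike hyperpolarization decaying over 30–80 ms, an
optional depolarizing hump) at each spike time on a 10-kHz grid, plus
white gaussian noise. With zero noise the spike-triggered average
reproduces the template exactly when spikes do not overlap within the
window.

## Literature aggregation

Packaged TSV transcriptions hold the published group values for plasma
osmolality (mOsm/kg), haematocrit (% packed cell volume), pituitary
hormone content (% of control) and plasma hormone concentration (pg/mL),
keyed by study, group (EU/SL), and day of salt loading. Rows are tagged
`obs` (printed observations), `printed_av` (the source's own per-study
average column) or `printed_delta`. Aggregation follows the original
two-stage rule: one value per study, then the mean of study means with
sample SD, SEM = SD/√n and 95% CI = mean ± 1.96·SEM. The normal z
rather than a t quantile is used because the printed CIs reverse-engineer
exactly to 1.96·SEM. Per-study averaging rules: plasma uses days >2;
pituitary uses days 5–8; haematocrit uses all salt-loaded values; the
day-7 aggregate uses day-7 values only.

Where a printed per-study average deviates from strict application of
the day rule (one oxytocin study's average is the all-days mean), the
fixture preserves the printed value, headline aggregates use printed
values, and the rule-based recomputation is available separately. Paired
deltas (SL − EU) are computed per matched study and summarized the same
way; their printed dispersions are SEMs. The day trend of
osmolality-change against duration is a least-squares slope through the
origin. No random-effects modelling or heterogeneity statistics are
applied — the aggregation is purely descriptive, and no inferential
hypothesis tests are performed anywhere in the package.

## Physiological arithmetic

Pure linear conversions with named constants: infusion dosimetry
(concentration × rate × time; 2 M × 26 µL/min × 30 min = 1.56 mmol);
predicted natraemia either *theoretical* (distribute the load over total
body water, 0.7 L/kg, so 1.56 mmol in a 350-g rat gives the exact
quotient 6.37 mM — commonly rounded to ~6.5) or *empirical*
(6.1 mM/mmol measured); osmolality rises by twice the [Na⁺] rise. The
two Na-per-mmol constants are mutually inconsistent in their sources, so
no default is provided — callers must name the mode. Expected firing
elevation uses 0.2 spikes/s per mOsm/kg; secretion arithmetic converts
ng/h to ng/day and integer % of pituitary content (half-away-from-zero
rounding); the firing-rate→plasma-vasopressin constant is 6.4 pg/mL per
spikes/s, linear over 1–6 spikes/s with a warning outside that regime.

## Problem sizes and tolerances in the test suite

Stochastic checks run at sizes chosen so sampling error sits well inside
the asserted bands while the full suite stays fast: the Poisson
reference train is 10,000 s at 5 spikes/s (~50,000 ISIs; CV within
±0.02 of 1, exponential skewness ≈2 and excess kurtosis ≈6 within 5%);
hazard flatness uses 100,000 ISIs (max/min bin ratio −1 < 0.15 over
0–290 ms); the phasic recovery runs 2 h of simulated time (recovered
burst statistics within 10% of realized truth, intraburst rate within
10% of target); DAP monotonicity uses three amplitudes at 5,000 s each;
programmed response effects are recovered within 2 SE of the simulation.
All generators are seeded; the whole suite runs in a few seconds.

## What the synthetic tests do and do not show

The generators emulate the statistical structure the analyses assume —
renewal firing with afterpotential-shaped hazards, alternating
burst/silence phasic patterns, plateau/transient/ramp response profiles,
template-plus-noise voltage. They do not emulate nonstationary basal
drift, bursting driven by activity-dependent plateau mechanisms,
correlated (non-renewal) ISI sequences, electrode drift or spike-height
instability, or multi-unit contamination. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to those real-data pathologies. Cell-level
population results from the original recordings (e.g. group rate
differences and osmotic-response slopes) are reproducible only from the
archived data, for which an adapter can be written against the deposited
workbook layout; here they are covered by recovery of the same effect
sizes programmed into synthetic experiments.

## Known limitations

- The hazard denominator follows the printed formula verbatim; users
  wanting the textbook at-risk estimator must opt in per call.
- The experiment sampler's additive-effect conversion is exact only for
  a Poisson base; programmed deltas under strong afterpotentials are
  approximate (documented first-order rescaling).
- The phasic generator's truncation floor makes very short bursts and
  silences (<6 s) unreachable at the default parameterization; stress
  tests lower the floor explicitly.
- Mode estimates at the 1-ms analysis default are noisy for broad ISI
  distributions; population comparisons of modes should use many cells
  or wider bins.
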