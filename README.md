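# magnospike

Spike-train analysis for magnocellular neuroendocrine neurones — the
oxytocin and vasopressin cells of the hypothalamic supraoptic nucleus —
built for *in vivo* extracellular recordings in euhydrated (EU),
salt-loaded (SL) and rehydrated (RE) rats, and for fully synthetic
replicas of such experiments.

It is aimed at electrophysiologists and modellers who work with spike
arrival times (0.1-ms resolution) plus intervention metadata, and covers:

- **ISI statistics** — coefficient of variation (CV = SD/mean of
  interspike intervals; 1 for a Poisson process), 1-ms ISI histograms,
  mode, bias-corrected skewness and excess kurtosis, population-averaged
  normalized distributions.
- **Hazard functions** — post-spike excitability in 10-ms bins,
  `hazard[t, t+10) = 100 · #ISIs ∈ [t, t+10) / #ISIs > t+10 ms`, with the
  peak sought below 90 ms, the asymptote averaged over 140–290 ms, and
  their difference ("peak hazard") indexing the depolarizing
  afterpotential (DAP).
- **Burst segmentation** — phasic firing split into bursts (≥5 s, ≥20
  spikes, intraburst ISIs ≤1 s) and interburst silences (>5 s), with
  burst statistics over complete bursts only, and a phasic/continuous
  classifier.
- **Stimulus responses** — CCK and phenylephrine (5-min pre/post windows,
  delta and % of basal), hypertonic NaCl infusion (30-s binned change
  from basal, 20–30 min response, slope per mmol infused through the
  origin), PEG hypovolaemia (30–45 min window), and peristimulus-time
  histograms (40-ms bins, % of pre-stimulation counts). CCK-based cell
  classification (excited > +0.3 spikes/s → oxytocin; inhibited → 
  continuous vasopressin; phasic overrides).
- **Spike-triggered averaging** — mean extracellular waveform aligned on
  the maximum negative deflection, baselined 10–15 ms pre-spike,
  normalized to unit spike height and presented positive-going.
- **Synthetic data** — a discrete-time renewal spike generator in which
  random synaptic input is gated by exponentially decaying
  afterpotentials, λ(Δt) = r·exp(−H·e^(−Δt/τ_H) + D·e^(−Δt/τ_D)); a
  phasic burst/silence generator; scripted experiments (CCK transients,
  infusion ramps); and voltage-trace synthesis for waveform tests.
- **Literature aggregation** — packaged transcriptions of published
  group means (plasma osmolality, haematocrit, pituitary content, plasma
  hormone) aggregated as study means ± SD with normal 95% CIs, plus the
  related physiological arithmetic (infusion dosimetry, predicted
  natraemia, expected firing elevation, secretion/depletion budgets).

## Worked example

```python
import numpy as np
from magnospike import (
    RenewalModelParams, calibrate_input_rate, simulate_postspike_renewal,
    extract_isis, isi_stats, hazard_function, hazard_summary,
)

# a vasopressin-like cell: 6 spikes/s with a strong HAP and a DAP
params = calibrate_input_rate(6.0, RenewalModelParams(
    input_rate=6.0, hap_amp=3.0, hap_tau=15.0,
    dap_amp=1.2, dap_tau=80.0, seed=42))
train = simulate_postspike_renewal(params, duration=3600.0)
isis = extract_isis(train)

stats = isi_stats(isis)
summ = hazard_summary(hazard_function(isis))
print(f"rate {train.n_spikes / train.duration:.2f} spikes/s  "
      f"CV {stats.cv:.2f}  mode {stats.mode:.1f} ms")
print(f"peak hazard {summ.peak_hazard:.1f}% at {summ.peak_time:.0f} ms "
      f"(asymptote {summ.asymptote:.1f}%)")
```

prints

```
rate 6.00 spikes/s  CV 1.09  mode 34.5 ms
peak hazard 3.2% at 40 ms (asymptote 5.7%)
```

The early ISI mode (~35 ms) reflects the relative refractoriness imposed
by the hyperpolarizing afterpotential, and the positive peak hazard above
the asymptote is the signature of the depolarizing afterpotential, which
also pushes the CV slightly above 1 by clustering spikes on its time
scale.

A command-line interface mirrors the library:

```bash
magnospike simulate --model phasic --duration 7200 --seed 42 --out cell.csv
magnospike bursts cell.csv
magnospike meta --table 7 --variable plasma_VP
magnospike calc secretion --rate-ng-h 14 --content-ng 875
magnospike demo --seed 42 --out demo/
```

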