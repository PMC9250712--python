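# Versioned scenario definitions for the synthetic corpus generator.
#
# Each scenario is a SyntheticSpec parameter set (seed and series_id are
# supplied by the corpus driver).  peak_month may be an integer 1-12 or
# "random" for a uniform per-series draw.
#
# Units: baseline/amplitude/noise_sd are persons per thousand; trend_slope
# is per-thousand per month; phase_jitter_sd is months.  noise_sd 0.07 at
# baseline 5 equals the binomial sampling noise of a one-million-person
# denominator (sqrt(5000)/1000), the realistic sampling regime for the
# large claims databases the generator emulates.
scenarios:
  # Spiky persistent/consistent peaks: the positive-concordance regime.
  # peak_sharpness 3 gives the epidemic-curve shape of strongly seasonal
  # diagnoses; a pure cosine (sharpness 1) is an ARMA(2,2) process that the
  # non-seasonal base of the AR test absorbs, so it is NOT that regime.
  strong-harmonic:
    years: 6
    baseline: 5.0
    amplitude: 2.0
    peak_month: random
    phase_jitter_sd: 0.0
    amplitude_decay: 0.0
    peak_sharpness: 3.0
    trend_slope: 0.01
    noise_sd: 0.2
  damped-peaks:
    years: 6
    baseline: 5.0
    amplitude: 2.0
    peak_month: random
    phase_jitter_sd: 0.0
    amplitude_decay: 0.3
    trend_slope: 0.0
    noise_sd: 0.2
  jittered-peaks:
    years: 6
    baseline: 5.0
    amplitude: 1.5
    peak_month: random
    phase_jitter_sd: 2.0
    amplitude_decay: 0.0
    trend_slope: 0.0
    noise_sd: 0.2
  high-variance-aperiodic:
    years: 6
    baseline: 10.0
    amplitude: 0.0
    peak_month: 1
    phase_jitter_sd: 0.0
    amplitude_decay: 0.0
    trend_slope: 0.0
    noise_sd: 1.5
  near-constant-null:
    years: 4
    baseline: 5.0
    amplitude: 0.0
    peak_month: 1
    phase_jitter_sd: 0.0
    amplitude_decay: 0.0
    trend_slope: 0.002
    noise_sd: 0.0
  white-noise-null:
    years: 4
    baseline: 5.0
    amplitude: 0.0
    peak_month: 1
    phase_jitter_sd: 0.0
    amplitude_decay: 0.0
    trend_slope: 0.0
    noise_sd: 0.07
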