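# Default time-frequency signatures for the five synthetic vocalization classes.
#
# These are parametric stand-ins chosen to be mutually distinguishable in the
# log-mel plane, not bioacoustically faithful species models. Users can retune
# any field here; `jitter` gives per-origin multiplicative jitter fractions
# applied when a dataset is generated (so origins within a class differ).
#
# Fields (see anurapam.calls.CallSignature):
#   carrier_freq  Hz    fundamental of the call
#   am_rate       Hz    pulse/trill amplitude-modulation rate (0 = no AM)
#   call_duration s     duration of one call element
#   n_repeats     -     repeats (ao_standard) or superposed voices (ec_chorus)
#   fm_sweep      Hz/s  linear frequency sweep rate (0 = constant pitch)
#   harmonics     -     number of harmonic partials (amplitude halves per partial)
#   rel_amplitude -     relative call level in (0, 1]

ec_standard:            # natterjack advertisement trill: pulsed ~1.5 kHz tone
  carrier_freq: 1500.0
  am_rate: 18.0
  call_duration: 1.4
  n_repeats: 1
  fm_sweep: 0.0
  harmonics: 2
  rel_amplitude: 1.0
  jitter: {carrier_freq: 0.06, am_rate: 0.15, call_duration: 0.20}

ec_chorus:              # several desynchronized, detuned trills superposed
  carrier_freq: 1500.0
  am_rate: 18.0
  call_duration: 1.0
  n_repeats: 4
  fm_sweep: 0.0
  harmonics: 2
  rel_amplitude: 1.0
  jitter: {carrier_freq: 0.06, am_rate: 0.15, call_duration: 0.10}

ec_amplexus:            # quiet, slow-pulsed, slightly lower tone
  carrier_freq: 1250.0
  am_rate: 6.0
  call_duration: 1.0
  n_repeats: 1
  fm_sweep: 0.0
  harmonics: 1
  rel_amplitude: 0.35
  jitter: {carrier_freq: 0.05, am_rate: 0.20, call_duration: 0.20}

ao_standard:            # midwife toad: short repeated flute-like whistle
  carrier_freq: 1150.0
  am_rate: 0.0
  call_duration: 0.12
  n_repeats: 6
  fm_sweep: 0.0
  harmonics: 1
  rel_amplitude: 0.9
  jitter: {carrier_freq: 0.05, call_duration: 0.15}

ao_distress:            # rising frequency-modulated alarm sweep
  carrier_freq: 1000.0
  am_rate: 0.0
  call_duration: 1.0
  n_repeats: 1
  fm_sweep: 2000.0
  harmonics: 2
  rel_amplitude: 1.0
  jitter: {carrier_freq: 0.06, fm_sweep: 0.15, call_duration: 0.15}
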