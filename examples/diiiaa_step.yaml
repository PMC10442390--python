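# CLI run configuration: DIIIAA leaky-state step (30 ms to +60 mV).
# Usage: navleak simulate examples/diiiaa_step.yaml -o diiiaa_step
#        navleak analyze peakss diiiaa_step.csv -o diiiaa
variant: DIIIAA
protocol: step
conditions:
  species:
    - {name: Na, valence: 1}
  conc_out: {Na: 57.5}
  conc_in: {Na: 12.0}
  temperature: 11.5
acquisition:
  filter_cutoff_kHz: 20.0
  noise_sigma: 0.0
  tau_clamp: 0.075
kind: ionic
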