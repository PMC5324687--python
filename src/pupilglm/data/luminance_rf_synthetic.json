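{
  "k": 3.0,
  "theta": 0.45,
  "c": 1.0,
  "t0": 0.2,
  "provenance": "SYNTHETIC stand-in luminance response kernel (gamma, peak at 1.1 s); not an empirically derived final-pathway kernel — replace with a measured luminance response function for real-data analyses"
}
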