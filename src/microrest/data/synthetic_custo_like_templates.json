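{
 "description": "SYNTHETIC stand-in for a normative 7-class resting-state microstate template set on a 32-channel 10-20-style montage. Generated by microrest.simulate.make_templates(32, 7, seed=20260929); not derived from any recorded EEG. Substitute a real template CSV for analyses of real data.",
 "k": 7,
 "n_channels": 32,
 "seed": 20260929,
 "class_labels": [
  "1/A",
  "2/B",
  "3/C",
  "4/D",
  "5/E",
  "6/F",
  "7/G"
 ]
}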