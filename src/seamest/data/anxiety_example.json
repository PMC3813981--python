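{
  "comment": "Bundled worked example: three doses of an anxiolytic vs placebo, endpoint = 8-week change in Hamilton Anxiety score (points), known SD 6, 71 subjects per arm per stage, futility boundary 0. Dose 2 is selected at stage 1.",
  "design": {"k": 3, "n1": 71, "n2": 71, "sigma": 6.0, "b": 0.0},
  "stage1_means": [-0.082, 0.413, 1.766, 1.567],
  "stage2_means": {"control": 0.049, "selected": 1.451},
  "true_means": {"control": 0.0, "experimental": [0.8, 1.5, 2.6]}
}
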