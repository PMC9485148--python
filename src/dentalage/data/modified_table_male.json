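{
  "name": "modified-southern-china-male",
  "sex": "male",
  "kind": "age_sum",
  "scores": {
    "31": {"A": null, "B": null, "C": 0.90, "D": 0.80, "E": 0.80, "F": 1.00, "G": 1.11, "H": 1.17},
    "32": {"A": null, "B": null, "C": 0.43, "D": 0.49, "E": 0.57, "F": 0.84, "G": 1.02, "H": 1.27},
    "33": {"A": null, "B": null, "C": null, "D": 0.03, "E": 0.24, "F": 0.37, "G": 0.85, "H": 1.48},
    "34": {"A": 0.19, "B": 0.72, "C": 0.97, "D": 1.44, "E": 1.91, "F": 2.62, "G": 3.14, "H": 3.66},
    "35": {"A": 0.05, "B": 0.03, "C": 0.07, "D": 0.16, "E": 0.20, "F": 0.27, "G": 0.24, "H": 0.70},
    "36": {"A": null, "B": null, "C": null, "D": 1.07, "E": 1.77, "F": 2.49, "G": 3.03, "H": 3.34},
    "37": {"A": 0.17, "B": 0.46, "C": 0.69, "D": 0.77, "E": 1.27, "F": 1.94, "G": 2.40, "H": 4.03}
  }
}
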