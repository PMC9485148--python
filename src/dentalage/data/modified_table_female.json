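{
  "name": "modified-southern-china-female",
  "sex": "female",
  "kind": "age_sum",
  "scores": {
    "31": {"A": null, "B": null, "C": 1.86, "D": 2.23, "E": 2.38, "F": 2.87, "G": 3.25, "H": 3.20},
    "32": {"A": null, "B": null, "C": null, "D": 0.30, "E": 0.33, "F": 0.50, "G": 0.80, "H": 0.71},
    "33": {"A": null, "B": null, "C": 0.63, "D": 0.57, "E": 0.65, "F": 1.14, "G": 1.81, "H": 2.11},
    "34": {"A": -1.10, "B": -0.17, "C": 0.19, "D": 0.47, "E": 0.69, "F": 1.47, "G": 1.83, "H": 2.53},
    "35": {"A": -0.20, "B": 0.01, "C": 0.29, "D": 0.18, "E": 0.37, "F": 0.37, "G": 0.58, "H": 1.60},
    "36": {"A": null, "B": null, "C": null, "D": 0.63, "E": 0.92, "F": 1.59, "G": 1.86, "H": 2.26},
    "37": {"A": 0.11, "B": 0.09, "C": 0.17, "D": 0.26, "E": 0.54, "F": 1.05, "G": 1.71, "H": 3.30}
  }
}
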