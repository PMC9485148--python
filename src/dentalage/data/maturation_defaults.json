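{
  "version": 2,
  "offset_sd": 0.4,
  "tooth_jitter_sd": 0.4,
  "attainment": {
    "female": {
      "31": {
        "A": null,
        "B": null,
        "C": null,
        "D": 2.25,
        "E": 2.34,
        "F": 5.17,
        "G": 5.31,
        "H": 7.85
      },
      "32": {
        "A": null,
        "B": null,
        "C": null,
        "D": null,
        "E": 2.65,
        "F": 5.54,
        "G": 5.65,
        "H": 8.85
      },
      "33": {
        "A": null,
        "B": null,
        "C": null,
        "D": 4.65,
        "E": 4.95,
        "F": 11.35,
        "G": 11.95,
        "H": 12.25
      },
      "34": {
        "A": null,
        "B": 1.95,
        "C": 2.11,
        "D": 4.91,
        "E": 5.02,
        "F": 8.57,
        "G": 8.78,
        "H": 12.55
      },
      "35": {
        "A": null,
        "B": 2.25,
        "C": 5.31,
        "D": 5.47,
        "E": 9.07,
        "F": 9.24,
        "G": 13.28,
        "H": 13.55
      },
      "36": {
        "A": null,
        "B": null,
        "C": null,
        "D": null,
        "E": 2.85,
        "F": 5.81,
        "G": 5.99,
        "H": 9.55
      },
      "37": {
        "A": null,
        "B": 2.35,
        "C": 2.57,
        "D": 5.83,
        "E": 6.04,
        "F": 10.06,
        "G": 10.39,
        "H": 14.95
      }
    },
    "male": {
      "31": {
        "A": null,
        "B": null,
        "C": null,
        "D": 2.6,
        "E": 2.69,
        "F": 5.52,
        "G": 5.66,
        "H": 8.2
      },
      "32": {
        "A": null,
        "B": null,
        "C": null,
        "D": 3.0,
        "E": 5.8,
        "F": 5.9,
        "G": 9.0,
        "H": 9.2
      },
      "33": {
        "A": null,
        "B": null,
        "C": null,
        "D": null,
        "E": 5.0,
        "F": 5.31,
        "G": 11.98,
        "H": 12.6
      },
      "34": {
        "A": null,
        "B": 2.3,
        "C": 2.46,
        "D": 5.26,
        "E": 5.37,
        "F": 8.92,
        "G": 9.13,
        "H": 12.9
      },
      "35": {
        "A": null,
        "B": 2.6,
        "C": 5.66,
        "D": 5.82,
        "E": 9.42,
        "F": 9.59,
        "G": 13.63,
        "H": 13.9
      },
      "36": {
        "A": null,
        "B": null,
        "C": null,
        "D": null,
        "E": 3.2,
        "F": 6.16,
        "G": 6.34,
        "H": 9.9
      },
      "37": {
        "A": null,
        "B": 2.7,
        "C": 2.92,
        "D": 6.18,
        "E": 6.39,
        "F": 10.41,
        "G": 10.74,
        "H": 15.3
      }
    }
  }
}
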