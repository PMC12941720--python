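{
 "apoe": {
  "C1": {
   "ambiguous": false,
   "diplotype": "e3/e3",
   "e4_carrier": false
  },
  "C2": {
   "ambiguous": false,
   "diplotype": "e3/e3",
   "e4_carrier": false
  },
  "GP1": {
   "ambiguous": false,
   "diplotype": "e3/e3",
   "e4_carrier": false
  },
  "GP2": {
   "ambiguous": false,
   "diplotype": "e3/e3",
   "e4_carrier": false
  },
  "GP3": {
   "ambiguous": true,
   "diplotype": "e2/e4",
   "e4_carrier": true
  },
  "P1": {
   "ambiguous": false,
   "diplotype": "e3/e3",
   "e4_carrier": false
  },
  "P2": {
   "ambiguous": false,
   "diplotype": "e3/e3",
   "e4_carrier": false
  }
 },
 "burden": {
  "carrier_comparison": {
   "carriers": {
    "display": "e4 carriers: n=1, mean 73.0 (single value)",
    "label": "e4 carriers",
    "max": 73.0,
    "mean": 73.0,
    "min": 73.0,
    "n": 1,
    "sd": null
   },
   "mean_difference": 23.666666666666664,
   "non_carriers": {
    "display": "non-carriers: n=6, mean 49.3 \u00b1 12.1, range: 33-67",
    "label": "non-carriers",
    "max": 67.0,
    "mean": 49.333333333333336,
    "min": 33.0,
    "n": 6,
    "sd": 12.07752734075426
   }
  },
  "contribution_percent": {
   "ABCA7": 46.070460704607044,
   "APOE": 5.420054200542006,
   "BIN1": 4.336043360433604,
   "CLU": 4.0650406504065035,
   "CR1": 10.29810298102981,
   "PICALM": 29.810298102981026
  },
  "gene_means": {
   "ABCA7": 24.285714285714285,
   "APOE": 2.857142857142857,
   "BIN1": 2.2857142857142856,
   "CLU": 2.142857142857143,
   "CR1": 5.428571428571429,
   "PICALM": 15.714285714285714
  },
  "generation_trend": {
   "intercept": 54.35294117647059,
   "r": -0.05591684563451278,
   "slope": -0.8823529411764711
  },
  "icc": {
   "icc": -0.6951153406010965,
   "k0": 2.2857142857142856,
   "msb": 18.38095238095238,
   "msw": 293.1666666666667
  },
  "overall": {
   "display": "family: n=7, mean 52.7 \u00b1 14.2, range: 33-73",
   "label": "family",
   "max": 73.0,
   "mean": 52.714285714285715,
   "min": 33.0,
   "n": 7,
   "sd": 14.197585307770776
  },
  "per_generation": [
   {
    "display": "Generation 1: n=3, mean 52.3 \u00b1 20.0, range: 33-73",
    "label": "Generation 1",
    "max": 73.0,
    "mean": 52.333333333333336,
    "min": 33.0,
    "n": 3,
    "sd": 20.033305601755625
   },
   {
    "display": "Generation 2: n=2, mean 56.0 \u00b1 15.6, range: 45-67",
    "label": "Generation 2",
    "max": 67.0,
    "mean": 56.0,
    "min": 45.0,
    "n": 2,
    "sd": 15.556349186104045
   },
   {
    "display": "Generation 3: n=2, mean 50.0 \u00b1 11.3, range: 42-58",
    "label": "Generation 3",
    "max": 58.0,
    "mean": 50.0,
    "min": 42.0,
    "n": 2,
    "sd": 11.313708498984761
   }
  ],
  "per_individual_gene_counts": {
   "C1": {
    "ABCA7": 28,
    "APOE": 1,
    "BIN1": 2,
    "CLU": 1,
    "CR1": 0,
    "PICALM": 10
   },
   "C2": {
    "ABCA7": 29,
    "APOE": 1,
    "BIN1": 4,
    "CLU": 1,
    "CR1": 6,
    "PICALM": 17
   },
   "GP1": {
    "ABCA7": 11,
    "APOE": 2,
    "BIN1": 4,
    "CLU": 0,
    "CR1": 16,
    "PICALM": 18
   },
   "GP2": {
    "ABCA7": 14,
    "APOE": 0,
    "BIN1": 0,
    "CLU": 6,
    "CR1": 4,
    "PICALM": 9
   },
   "GP3": {
    "ABCA7": 41,
    "APOE": 10,
    "BIN1": 0,
    "CLU": 0,
    "CR1": 3,
    "PICALM": 19
   },
   "P1": {
    "ABCA7": 37,
    "APOE": 4,
    "BIN1": 0,
    "CLU": 6,
    "CR1": 3,
    "PICALM": 17
   },
   "P2": {
    "ABCA7": 10,
    "APOE": 2,
    "BIN1": 6,
    "CLU": 1,
    "CR1": 6,
    "PICALM": 20
   }
  },
  "per_individual_total": {
   "C1": 42,
   "C2": 58,
   "GP1": 51,
   "GP2": 33,
   "GP3": 73,
   "P1": 67,
   "P2": 45
  },
  "sibling_discordance": [
   {
    "delta": 16.0,
    "gene_deltas": {
     "ABCA7": 1,
     "APOE": 0,
     "BIN1": 2,
     "CLU": 0,
     "CR1": 6,
     "PICALM": 7
    },
    "pair": [
     "C1",
     "C2"
    ],
    "relative_percent": 38.095238095238095
   }
  ],
  "snps_per_gene": {
   "ABCA7": 48,
   "APOE": 9,
   "BIN1": 5,
   "CLU": 6,
   "CR1": 25,
   "PICALM": 37
  }
 },
 "mendelian_violations": [],
 "methylation": {
  "cluster_merges": [
   {
    "cluster_a": [
     "GP2"
    ],
    "cluster_b": [
     "P2"
    ],
    "height": 0.15035213973203043
   },
   {
    "cluster_a": [
     "P1"
    ],
    "cluster_b": [
     "C2"
    ],
    "height": 0.1551873685162552
   },
   {
    "cluster_a": [
     "GP3"
    ],
    "cluster_b": [
     "C1"
    ],
    "height": 0.1618045860011391
   },
   {
    "cluster_a": [
     "GP2",
     "P2"
    ],
    "cluster_b": [
     "P1",
     "C2"
    ],
    "height": 0.17105513842033512
   },
   {
    "cluster_a": [
     "GP2",
     "P1",
     "P2",
     "C2"
    ],
    "cluster_b": [
     "GP3",
     "C1"
    ],
    "height": 0.18448118488886606
   },
   {
    "cluster_a": [
     "GP1"
    ],
    "cluster_b": [
     "GP2",
     "GP3",
     "P1",
     "P2",
     "C1",
     "C2"
    ],
    "height": 0.2807756964108539
   }
  ],
  "filter_counts": {
   "cross_reactive": 0,
   "detection_p": 3,
   "sex_chromosome": 0,
   "snp_overlap": 0
  },
  "gene_mean_beta": {
   "ABCA7": {
    "C1": 0.5053975454545454,
    "C2": 0.5094998181818181,
    "GP1": 0.48026409090909095,
    "GP2": 0.4972956363636364,
    "GP3": 0.49942945454545457,
    "P1": 0.49832718181818175,
    "P2": 0.49794863636363634
   },
   "APOE": {
    "C1": 0.49527566666666667,
    "C2": 0.4990306666666667,
    "GP1": 0.4749843333333333,
    "GP2": 0.5035665833333333,
    "GP3": 0.49120141666666667,
    "P1": 0.4973626666666666,
    "P2": 0.49983758333333334
   },
   "BIN1": {
    "C1": 0.49398116666666664,
    "C2": 0.49644625,
    "GP1": 0.47408175,
    "GP2": 0.502118,
    "GP3": 0.49891225,
    "P1": 0.49828574999999997,
    "P2": 0.5023225833333334
   },
   "CLU": {
    "C1": 0.496419,
    "C2": 0.48856974999999997,
    "GP1": 0.47781925,
    "GP2": 0.49931041666666665,
    "GP3": 0.5058730833333334,
    "P1": 0.4961241666666667,
    "P2": 0.4965064166666666
   },
   "CR1": {
    "C1": 0.5030379090909091,
    "C2": 0.5024591818181818,
    "GP1": 0.47137063636363635,
    "GP2": 0.49775181818181813,
    "GP3": 0.49946781818181807,
    "P1": 0.500243090909091,
    "P2": 0.49688436363636357
   },
   "PICALM": {
    "C1": 0.50310175,
    "C2": 0.49543825,
    "GP1": 0.47483158333333336,
    "GP2": 0.5007694166666666,
    "GP3": 0.4984416666666667,
    "P1": 0.50168925,
    "P2": 0.49715033333333336
   }
  },
  "genotype_methylation_r": {
   "ABCA7": 0.5073365878562066,
   "APOE": -0.2294027774871562,
   "BIN1": -0.27150784782238774,
   "CLU": 0.269402119841808,
   "CR1": -0.9350377591057525,
   "PICALM": -0.3985760717543084
  },
  "n_probes_input": 90,
  "n_probes_kept": 87,
  "probes_per_gene": {
   "ABCA7": 11,
   "APOE": 12,
   "BIN1": 12,
   "CLU": 12,
   "CR1": 11,
   "PICALM": 12
  }
 },
 "pedigree": {
  "affected": [
   "GP1"
  ],
  "family_id": "SYN1",
  "generations": {
   "C1": 3,
   "C2": 3,
   "GP1": 1,
   "GP2": 1,
   "GP3": 1,
   "P1": 2,
   "P2": 2
  },
  "n_blood_relatives": 7,
  "n_members": 7,
  "probands": [
   "C1",
   "C2"
  ]
 },
 "qc": {
  "n_in_region": 320,
  "n_panel": 320,
  "n_scored": 130,
  "removed": {
   "missing_calls": 7,
   "monomorphic": 183,
   "multiallelic": 0,
   "no_risk_designation": 0
  }
 }
}
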