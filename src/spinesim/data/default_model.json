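{
  "archetypes": {
    "filopodium": {
      "head_ratio": {
        "mu": 0.04879016416943205,
        "sigma": 0.111
      },
      "length": {
        "mu": 1.7047480922384253,
        "sigma": 0.18
      },
      "neck": {
        "mu": -1.7147984280919266,
        "sigma": 0.23125
      },
      "weight": 0.065
    },
    "mushroom": {
      "head_ratio": {
        "mu": 0.5596157879354227,
        "sigma": 0.18500000000000003
      },
      "length": {
        "mu": 0.09531017980432493,
        "sigma": 0.36
      },
      "neck": {
        "mu": -1.2039728043259361,
        "sigma": 0.24050000000000002
      },
      "weight": 0.25972222222222224
    },
    "stubby": {
      "head_ratio": {
        "mu": 0.13976194237515863,
        "sigma": 0.1665
      },
      "length": {
        "mu": -0.35667494393873245,
        "sigma": 0.36
      },
      "neck": {
        "mu": -1.1394342831883648,
        "sigma": 0.25900000000000006
      },
      "weight": 0.25972222222222224
    },
    "thin": {
      "head_ratio": {
        "mu": 0.22314355131420976,
        "sigma": 0.20350000000000001
      },
      "length": {
        "mu": 0.3364722366212129,
        "sigma": 0.396
      },
      "neck": {
        "mu": -1.3470736479666092,
        "sigma": 0.25900000000000006
      },
      "weight": 0.4155555555555556
    }
  },
  "area_kappa": 1.3,
  "area_noise_halfwidth": 0.95,
  "sample_effect_sigma": 0.0
}
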