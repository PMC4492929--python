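{
  "small": {
    "subset": "small",
    "w0": 0.74345,
    "weights": {
      "d_ie": 0.03538,
      "dd_ee": 0.24695,
      "dd_ve": 0.1405,
      "dd_sp": 0.26,
      "dd_sn": 0.00354,
      "dd_s": 0.17197,
      "dd_hydr": 0.0,
      "d_hb": 0.0,
      "interface_mt": 1.67e-4,
      "dd_sasa_over_interface": 7.75803
    },
    "pvalues": {
      "w0": 2.61e-6,
      "d_ie": 1.57e-6,
      "dd_ee": 1.83e-7,
      "dd_ve": 8.99e-6,
      "dd_sp": 2.77e-6,
      "dd_sn": 0.029,
      "dd_s": 0.098,
      "interface_mt": 0.0122,
      "dd_sasa_over_interface": 0.00279
    },
    "n_cases": 612,
    "slope": -2.3058e-5,
    "y_intercept": 1.0
  },
  "large": {
    "subset": "large",
    "w0": 2.68491,
    "weights": {
      "d_ie": 0.053,
      "dd_ee": 0.38921,
      "dd_ve": 0.18347,
      "dd_sp": 0.44347,
      "dd_sn": 0.0,
      "dd_s": 0.1848,
      "dd_hydr": 0.55761,
      "d_hb": 0.03585,
      "interface_mt": 6.37356e-4,
      "dd_sasa_over_interface": 0.0
    },
    "pvalues": {
      "w0": 0.0,
      "d_ie": 1.63e-5,
      "dd_ee": 0.0,
      "dd_ve": 6.66e-16,
      "dd_sp": 2.22e-16,
      "dd_s": 0.00972,
      "dd_hydr": 2.1e-5,
      "d_hb": 0.0924,
      "interface_mt": 3.04e-6
    },
    "n_cases": 714,
    "slope": -7.0929e-7,
    "y_intercept": 1.0
  },
  "all": {
    "subset": "all",
    "w0": 1.81729,
    "weights": {
      "d_ie": 0.06648,
      "dd_ee": 0.39117,
      "dd_ve": 0.18732,
      "dd_sp": 0.43118,
      "dd_sn": 0.0,
      "dd_s": 0.20841,
      "dd_hydr": -0.6731,
      "d_hb": 0.0,
      "interface_mt": 4.64209e-4,
      "dd_sasa_over_interface": 9.82407
    },
    "pvalues": {
      "w0": 0.0,
      "d_ie": 0.0,
      "dd_ee": 0.0,
      "dd_ve": 0.0,
      "dd_sp": 0.0,
      "dd_s": 2.0e-4,
      "dd_hydr": 1.48e-10,
      "interface_mt": 3.64e-10,
      "dd_sasa_over_interface": 1.18e-5
    },
    "n_cases": 1326
  }
}
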