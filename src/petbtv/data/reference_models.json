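{
  "discovery_st": {
    "display_name": "Discovery ST",
    "intercept": 90.68,
    "coefficients": {"x2": -62.44, "fwhm": 1.05},
    "selection_order": ["x2", "fwhm"],
    "multiple_r2": 0.91,
    "shrinkage": -0.008,
    "standardized_beta": {"x2": -0.91, "fwhm": 0.23},
    "partial_r2": {"x2": 0.85, "fwhm": 0.06}
  },
  "discovery_ste": {
    "display_name": "Discovery STE",
    "intercept": 88.68,
    "coefficients": {"x2": -59.39, "fwhm": 1.03},
    "selection_order": ["x2", "fwhm"],
    "multiple_r2": 0.87,
    "shrinkage": 0.004,
    "standardized_beta": {"x2": -0.90, "fwhm": 0.23},
    "partial_r2": {"x2": 0.82, "fwhm": 0.05}
  },
  "discovery_600": {
    "display_name": "Discovery 600",
    "intercept": 93.52,
    "coefficients": {"x2": -64.38, "fwhm": 0.99},
    "selection_order": ["x2", "fwhm"],
    "multiple_r2": 0.92,
    "shrinkage": 0.000,
    "standardized_beta": {"x2": -0.93, "fwhm": 0.20},
    "partial_r2": {"x2": 0.88, "fwhm": 0.04}
  },
  "discovery_690": {
    "display_name": "Discovery 690",
    "intercept": 63.04,
    "coefficients": {"area": -0.015, "x2": -40.51, "fwhm": 1.92},
    "selection_order": ["x2", "fwhm", "area"],
    "multiple_r2": 0.74,
    "shrinkage": 0.007,
    "standardized_beta": {"x2": -0.61, "fwhm": 0.54, "area": 0.22},
    "partial_r2": {"x2": 0.40, "fwhm": 0.29, "area": 0.05}
  },
  "biograph_hirez": {
    "display_name": "Biograph Hi-REZ",
    "intercept": 88.19,
    "coefficients": {"x2": -56.18, "fwhm": 0.67},
    "selection_order": ["x2", "fwhm"],
    "multiple_r2": 0.92,
    "shrinkage": -0.012,
    "standardized_beta": {"x2": -0.95, "fwhm": 0.10},
    "partial_r2": {"x2": 0.91, "fwhm": 0.01}
  },
  "biograph_truev": {
    "display_name": "Biograph TRUEV",
    "intercept": 90.43,
    "coefficients": {"x2": -61.86, "fwhm": 0.95},
    "selection_order": ["x2", "fwhm"],
    "multiple_r2": 0.89,
    "shrinkage": -0.013,
    "standardized_beta": {"x2": -0.91, "fwhm": 0.19},
    "partial_r2": {"x2": 0.85, "fwhm": 0.04}
  },
  "gemini_xl": {
    "display_name": "Gemini XL",
    "intercept": 92.04,
    "coefficients": {"area": 0.0025, "x2": -59.15},
    "selection_order": ["x2", "area"],
    "multiple_r2": 0.82,
    "shrinkage": 0.067,
    "standardized_beta": {"x2": -0.89, "area": 0.27},
    "partial_r2": {"x2": 0.74, "area": 0.08}
  },
  "gemini_tf": {
    "display_name": "Gemini TF",
    "intercept": 88.57,
    "coefficients": {"area": 0.0027, "x2": -57.44},
    "selection_order": ["x2", "area"],
    "multiple_r2": 0.84,
    "shrinkage": -0.009,
    "standardized_beta": {"x2": -0.88, "area": 0.28},
    "partial_r2": {"x2": 0.76, "area": 0.08}
  }
}
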