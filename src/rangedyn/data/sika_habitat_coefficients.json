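{
  "description": "Published best habitat-suitability logistic model for sika deer in Japan, fitted to the 1978 national 5-km-mesh survey. Blocks: land use (FR, WS, AG, AG^2, BT), climate (snow cover period with region main effect and SCP x region interaction; Hokkaido is the reference region), topography (mean slope). Standard errors are back-calculated from the published 95% confidence intervals.",
  "formula": {
    "include_lu": true,
    "climate": "scp",
    "include_topo": true,
    "autocov": null
  },
  "coefficients": {
    "intercept": 1.236,
    "scp": -0.036,
    "rgn_other": -6.511,
    "scp_x_rgn": 0.020,
    "fr": 4.273,
    "ws": 3.623,
    "ag": 5.264,
    "ag2": -3.061,
    "bt": -2.894,
    "sl": 0.115
  },
  "ci95": {
    "intercept": [-0.479, 2.951],
    "scp": [-0.040, -0.032],
    "rgn_other": [-7.146, -5.876],
    "scp_x_rgn": [0.016, 0.024],
    "fr": [2.566, 5.980],
    "ws": [1.818, 5.428],
    "ag": [3.451, 7.077],
    "ag2": [-4.088, -2.034],
    "bt": [-5.738, -0.050],
    "sl": [0.103, 0.127]
  },
  "stderr": {
    "intercept": 0.875,
    "scp": 0.00204,
    "rgn_other": 0.32398,
    "scp_x_rgn": 0.00204,
    "fr": 0.87092,
    "ws": 0.92092,
    "ag": 0.925,
    "ag2": 0.52398,
    "bt": 1.45102,
    "sl": 0.00612
  },
  "loglik": NaN,
  "n": 15256
}
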