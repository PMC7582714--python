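{
  "kcat_A": {
    "value": 1.0,
    "unit": "1/s"
  },
  "kcat_B": {
    "value": 0.5,
    "unit": "1/s"
  },
  "km_0": {
    "value": 60.0,
    "unit": "uM"
  },
  "km_A": {
    "value": 60.0,
    "unit": "uM"
  },
  "km_B": {
    "value": 10.0,
    "unit": "uM"
  },
  "K_AU": {
    "value": 0.01,
    "unit": "1/uM"
  },
  "K_BU": {
    "value": 40.0,
    "unit": "1/uM"
  },
  "K_AL": {
    "value": 0.005,
    "unit": "1/uM"
  },
  "K_BL": {
    "value": 53.001719882880046,
    "unit": "1/uM"
  },
  "K_BI": {
    "value": 0.0,
    "unit": "1/uM"
  },
  "K_AI": {
    "value": 0.0,
    "unit": "1/uM"
  },
  "L_U": {
    "value": 3.1085214232341274e-06,
    "unit": "dimensionless"
  },
  "L_L": {
    "value": 4.0192821798701915e-05,
    "unit": "dimensionless"
  },
  "n": {
    "value": 3,
    "unit": "sites"
  },
  "m": {
    "value": 0,
    "unit": "sites"
  },
  "sigma_A": {
    "value": 1.0,
    "unit": "dimensionless"
  },
  "sigma_B": {
    "value": 1.0,
    "unit": "dimensionless"
  },
  "temperature_K": {
    "value": 310.15,
    "unit": "K"
  },
  "fixture_choices": [
    "kcat_A",
    "kcat_B",
    "km_0",
    "km_A",
    "km_B",
    "K_AU",
    "K_AL"
  ]
}
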