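{
  "kcat_A": {
    "value": 0.8,
    "unit": "1/s"
  },
  "kcat_B": {
    "value": 0.4,
    "unit": "1/s"
  },
  "km_0": {
    "value": 40.0,
    "unit": "uM"
  },
  "km_A": {
    "value": 40.0,
    "unit": "uM"
  },
  "km_B": {
    "value": 8.0,
    "unit": "uM"
  },
  "K_AU": {
    "value": 0.15,
    "unit": "1/uM"
  },
  "K_BU": {
    "value": 600.0,
    "unit": "1/uM"
  },
  "K_AL": {
    "value": 0.08,
    "unit": "1/uM"
  },
  "K_BL": {
    "value": 848.0275181260807,
    "unit": "1/uM"
  },
  "K_BI": {
    "value": 2.0,
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
    "value": 2,
    "unit": "sites"
  },
  "m": {
    "value": 1,
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
    "K_AL",
    "K_BI"
  ]
}
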