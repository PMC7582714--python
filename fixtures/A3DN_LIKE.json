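{
  "kcat_A": {
    "value": 1.5,
    "unit": "1/s"
  },
  "kcat_B": {
    "value": 1.5,
    "unit": "1/s"
  },
  "km_0": {
    "value": 80.0,
    "unit": "uM"
  },
  "km_A": {
    "value": 80.0,
    "unit": "uM"
  },
  "km_B": {
    "value": 30.0,
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
    "value": 0.040002352962490655,
    "unit": "dimensionless"
  },
  "L_L": {
    "value": 0.20000588231972244,
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
    "K_BI",
    "L_L"
  ]
}
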