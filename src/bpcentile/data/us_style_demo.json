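{
 "name": "us_style_demo",
 "params": {
  "dbp": {
   "F": {
    "alpha": 64.0,
    "beta": [
     0.8,
     0.0,
     0.0,
     0.0
    ],
    "gamma": [
     0.6,
     0.0,
     0.0,
     0.0
    ],
    "sigma": 9.0
   },
   "M": {
    "alpha": 63.5,
    "beta": [
     0.8,
     0.0,
     0.0,
     0.0
    ],
    "gamma": [
     0.6,
     0.0,
     0.0,
     0.0
    ],
    "sigma": 9.5
   }
  },
  "sbp": {
   "F": {
    "alpha": 105.0,
    "beta": [
     1.5,
     0.0,
     0.0,
     0.0
    ],
    "gamma": [
     1.2,
     0.0,
     0.0,
     0.0
    ],
    "sigma": 10.0
   },
   "M": {
    "alpha": 106.0,
    "beta": [
     1.6,
     0.0,
     0.0,
     0.0
    ],
    "gamma": [
     1.3,
     0.0,
     0.0,
     0.0
    ],
    "sigma": 10.5
   }
  }
 },
 "provenance": "Synthetic demonstration coefficients in the published-equation functional form (quartic in age-10 and height z). NOT published values.",
 "requires_height": true,
 "type": "gaussian_poly"
}
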