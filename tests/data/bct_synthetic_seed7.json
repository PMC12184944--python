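{
  "schema_version": "1.0",
  "family": "BCT",
  "outcome": {
    "name": "synthetic score",
    "units": "",
    "support": "positive-real"
  },
  "predictors": [
    {
      "name": "x1",
      "range": [
        0.0,
        1.0
      ]
    }
  ],
  "parameters": {
    "mu": {
      "link": "log",
      "intercept": 4.723038077248285,
      "linear": [
        {
          "name": "x1",
          "coef": -0.09991685754438728
        }
      ],
      "splines": [
        {
          "name": "x1",
          "degree": 3,
          "range": [
            0.0,
            1.0
          ],
          "ndx": 8,
          "coefficients": [
            -0.016167447347655933,
            -0.014716729068703586,
            0.01761047898815762,
            0.005738011050689512,
            -0.009228406655027561,
            0.0025870281595378386,
            0.011195466694951858,
            0.013738154051192782,
            -0.008705579648536296,
            -0.009411160154316426,
            0.007360183929710184
          ]
        }
      ]
    },
    "sigma": {
      "link": "log",
      "intercept": -1.1324346930084144,
      "linear": [
        {
          "name": "x1",
          "coef": 0.061937535429299084
        }
      ],
      "splines": [
        {
          "name": "x1",
          "degree": 3,
          "range": [
            0.0,
            1.0
          ],
          "ndx": 8,
          "coefficients": [
            0.06441591775767426,
            0.04148630877290737,
            0.02593389846065383,
            0.0037217381566312935,
            0.0008864324354859177,
            -0.014399547276531935,
            -0.011127976013957694,
            -0.009237486778273865,
            -0.01149195879661663,
            -0.04184522297216209,
            -0.048342103745810425
          ]
        }
      ]
    },
    "nu": {
      "link": "identity",
      "intercept": 1.051371380490387,
      "linear": [
        {
          "name": "x1",
          "coef": 0.016153281811376305
        }
      ],
      "splines": []
    },
    "tau": {
      "link": "log",
      "intercept": 1.7581436560226165,
      "linear": [
        {
          "name": "x1",
          "coef": 0.0017647058249392333
        }
      ],
      "splines": []
    }
  },
  "provenance": {
    "source": "synthetic fixture",
    "seed": 7
  }
}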