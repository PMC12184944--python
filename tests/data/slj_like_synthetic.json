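{
  "schema_version": "1.0",
  "family": "BCT",
  "outcome": {
    "name": "Standing Long Jump",
    "units": "cm",
    "support": "positive-real"
  },
  "predictors": [
    {
      "name": "nage",
      "raw_name": "age",
      "transform": {
        "power": 0.5,
        "shift": 0.0,
        "scale": 1.0
      },
      "range": [
        2.24,
        4.47
      ]
    }
  ],
  "parameters": {
    "mu": {
      "link": "log",
      "intercept": 3.6,
      "linear": [
        {
          "name": "nage",
          "coef": 0.42
        }
      ],
      "splines": [
        {
          "name": "nage",
          "degree": 3,
          "range": [
            2.24,
            4.47
          ],
          "ndx": 20,
          "coefficients": [
            0.020981076109584388,
            0.01564092788659353,
            0.0144623833354193,
            0.03220098699658584,
            0.030780185107514325,
            -0.01514113488264935,
            -0.019381311768923153,
            -0.02112782581723275,
            0.005509943508766341,
            -0.007413715267119876,
            -0.0020669687383266903,
            -0.004437544333881337,
            -0.019854777473280252,
            -0.020386825202740357,
            0.009080547433595196,
            -0.03193936976587345,
            0.011390098606684752,
            -0.001482172046462997,
            0.0019207653119276084,
            0.025572957335196017,
            0.009505810817710235,
            -0.014792695681258017,
            -0.01902134147182933
          ]
        }
      ]
    },
    "sigma": {
      "link": "log",
      "intercept": -1.7719568419318752,
      "linear": [
        {
          "name": "nage",
          "coef": -0.014460181941996733
        }
      ],
      "splines": [
        {
          "name": "nage",
          "degree": 3,
          "range": [
            2.24,
            4.47
          ],
          "ndx": 20,
          "coefficients": [
            -0.02394568959658059,
            -0.02918160688288432,
            -0.0328301036438257,
            -0.03133151047581379,
            -0.033928007058915285,
            -0.013900156776398949,
            0.003452196735636112,
            0.010122593703666277,
            0.012030008263878629,
            0.023858880834451535,
            0.013323224989922618,
            0.025748326540246703,
            0.019819756089696827,
            0.029958155744371093,
            0.02720089562357575,
            0.011580336389134908,
            -0.0015376305465313739,
            -0.006576369481155048,
            -0.007971248139147694,
            -0.006627434559330864,
            -0.00536303683106551,
            0.00030408025930323684,
            0.015794338817765527
          ]
        }
      ]
    },
    "nu": {
      "link": "identity",
      "intercept": 1.0,
      "linear": [
        {
          "name": "nage",
          "coef": 0.08404204570695362
        }
      ],
      "splines": [
        {
          "name": "nage",
          "degree": 3,
          "range": [
            2.24,
            4.47
          ],
          "ndx": 20,
          "coefficients": [
            0.04846090539643216,
            0.053426808188421805,
            0.04606060219554511,
            0.03704320872830969,
            0.040354181517205615,
            0.02973552128120495,
            0.01849867347603549,
            0.004729714138188304,
            -0.00969235793791369,
            -0.011499176480349822,
            0.001058829439350907,
            -0.0001812062638138906,
            -0.007132583978587202,
            -0.0098887539861744,
            0.00013500842348237313,
            -0.0009938427013940349,
            -0.014997742323372941,
            -0.02065743836025908,
            -0.0377224989429099,
            -0.03995751695302021,
            -0.04757781637944455,
            -0.040002292553797524,
            -0.03920022592313916
          ]
        }
      ]
    },
    "tau": {
      "link": "log",
      "intercept": 2.302585092994046,
      "linear": [
        {
          "name": "nage",
          "coef": -0.03522216811623522
        }
      ],
      "splines": [
        {
          "name": "nage",
          "degree": 3,
          "range": [
            2.24,
            4.47
          ],
          "ndx": 20,
          "coefficients": [
            -0.0035082996200771,
            -0.005419520010604922,
            -0.0004821472796515728,
            0.006033631281284502,
            0.006995487804544216,
            0.021350098822728196,
            -9.781905011859663e-06,
            -0.015993733329013233,
            -0.01430074593912751,
            -0.005282225178322957,
            -0.005560352887857653,
            -0.02741279284368868,
            -0.020573816541386854,
            -0.014453677981278489,
            -0.010563724758950567,
            -0.003079332550709498,
            0.00013687911800027049,
            0.0023043177308105364,
            0.0045967276694829085,
            0.007698722861665824,
            0.023928902127200717,
            0.028953388261138635,
            0.024641995148825105
          ]
        }
      ]
    }
  },
  "provenance": {
    "source": "synthetic stand-in shaped like the published SLJ-boys GAMLSS norms report",
    "published_fields": [
      "family",
      "predictor transform nage = age^(1/2)",
      "mu link/intercept/linear coefficient",
      "spline range, degree, ndx (all blocks)"
    ],
    "synthetic_fields": [
      "all spline coefficients",
      "sigma/nu/tau intercepts and linear coefficients"
    ]
  }
}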