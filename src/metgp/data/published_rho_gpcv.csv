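year,location,M1,M2,M3,M4,M5,M6,M7,M8,M9,repeatability,best,nonconverged,nonpd
2009,G-L1,0.469,0.473,0.462,0.481,0.448,0.455,0.474,0.481,0.478,0.376,M8,,
2009,G-L2,0.271,0.272,0.279,0.280,0.282,0.288,0.282,0.270,0.269,0.177,M6,,
2009,G-L3,0.347,0.344,0.351,0.350,0.345,0.339,0.350,0.355,0.355,0.264,M8,,
2009,G-L4,0.595,0.593,0.597,0.602,0.592,0.594,0.602,0.592,0.598,0.440,M4,,
2009,G-L5,0.495,0.514,0.506,0.505,0.519,0.527,,0.514,0.529,0.303,M9,M7,
2009,G-L6,0.393,0.398,0.357,0.372,0.359,0.360,0.369,0.372,0.378,0.077,M2,,
2009,G-L7,0.596,0.594,0.586,0.599,0.578,0.565,0.591,0.584,0.577,0.299,M4,,
2009,P-L1,0.127,0.118,0.132,0.138,0.116,0.114,0.138,0.174,0.167,0.225,M8,,
2009,P-L2,0.301,0.306,0.303,0.310,0.307,0.309,0.310,0.323,0.323,0.338,M9,,
2009,P-L3,-0.154,-0.165,-0.153,-0.154,-0.169,-0.172,-0.154,-0.158,-0.175,0.247,,,
2009,P-L4,0.520,0.518,0.527,0.525,0.520,0.522,0.525,0.558,0.555,0.362,M8,,
2010,G-L1,0.428,0.471,0.426,0.432,0.464,0.478,0.431,0.466,0.475,0.263,M6,,
2010,G-L2,0.394,0.392,0.399,0.407,0.400,0.398,0.406,0.401,0.400,0.248,M4,,M9
2010,G-L4,0.470,0.472,0.477,0.476,0.478,0.477,0.477,0.404,0.424,0.326,M3,,
2010,G-L5,0.469,0.485,0.471,0.469,0.476,0.486,0.469,0.479,0.487,0.407,M9,,
2010,G-L6,0.576,0.583,0.601,0.612,0.601,0.608,0.611,0.619,0.618,0.310,M8,,
2010,G-L7,0.520,0.552,0.557,0.564,0.541,0.556,0.565,0.579,0.574,0.298,M8,,
2010,G-L8,0.589,0.600,0.599,0.597,0.605,0.605,0.598,0.603,0.607,0.540,M9,,
2010,P-L1,0.327,0.334,0.327,0.327,0.326,0.333,0.327,0.327,0.337,0.439,M9,,
2010,P-L2,0.277,0.310,0.275,0.266,0.275,0.309,0.268,0.311,0.307,0.436,M8,,
2010,P-L3,0.461,0.466,0.461,0.462,0.459,0.467,0.461,0.459,0.467,0.416,M6;M9,,
2010,P-L4,0.314,0.322,0.317,0.316,0.315,0.317,0.317,0.317,0.315,0.360,M2,,
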