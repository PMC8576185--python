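# HeartMate III-style surrogate pump pressure-flow table (synthetic).
# Analytic centrifugal characteristic Q = sqrt(max(A*(w/1000)^2 - dP, 0)/C2),
# A = 3.8 mmHg (zero-flow head ~95 mmHg at 5000 RPM, scaling with speed^2),
# C2 = 0.00444 mmHg/(ml/s)^2 (dQ/ddP ~ 1.5 ml/s/mmHg at the operating point),
# clamped at zero flow.  Replace with a manufacturer table of the same
# layout if available.
# units: l/min
rpm,0,5,10,15,20,25,30,35,40,45,50,55,60,65,70,75,80,85,90,95,100,105,110,115,120,125,130,135,140,145,150
2000,3.511,2.876,2.053,0.403,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
2250,3.949,3.398,2.737,1.854,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
2500,4.388,3.899,3.339,2.664,1.744,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
2750,4.827,4.387,3.898,3.337,2.662,1.741,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
3000,5.266,4.866,4.430,3.946,3.393,2.731,1.845,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
3250,5.705,5.338,4.943,4.515,4.041,3.503,2.867,2.041,0.334,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
3500,6.144,5.804,5.444,5.058,4.640,4.180,3.663,3.060,2.305,1.121,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
3750,6.582,6.267,5.935,5.583,5.207,4.802,4.359,3.866,3.301,2.616,1.669,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
4000,7.021,6.726,6.418,6.094,5.752,5.388,4.997,4.574,4.107,3.579,2.959,2.169,0.805,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
4250,7.460,7.183,6.895,6.595,6.280,5.948,5.597,5.222,4.819,4.378,3.887,3.325,2.646,1.717,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
4500,7.899,7.638,7.368,7.087,6.795,6.490,6.170,5.832,5.474,5.090,4.675,4.219,3.707,3.113,2.374,1.257,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
4750,8.338,8.091,7.836,7.573,7.301,7.018,6.723,6.414,6.090,5.747,5.383,4.992,4.568,4.101,3.572,2.951,2.157,0.773,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
5000,8.777,8.542,8.302,8.054,7.798,7.534,7.260,6.975,6.678,6.367,6.040,5.695,5.327,4.932,4.502,4.027,3.487,2.847,2.013,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
5250,9.215,8.993,8.764,8.530,8.289,8.041,7.784,7.520,7.245,6.960,6.662,6.350,6.023,5.676,5.307,4.910,4.479,4.000,3.457,2.810,1.960,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
5500,9.654,9.442,9.225,9.002,8.774,8.540,8.299,8.051,7.796,7.531,7.257,6.972,6.675,6.364,6.037,5.691,5.323,4.928,4.498,4.022,3.482,2.840,2.003,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
5750,10.093,9.890,9.683,9.471,9.255,9.033,8.806,8.573,8.333,8.086,7.831,7.568,7.295,7.012,6.717,6.408,6.083,5.740,5.375,4.984,4.559,4.091,3.561,2.937,2.138,0.719,0.000,0.000,0.000,0.000,0.000
6000,10.532,10.338,10.140,9.938,9.732,9.521,9.306,9.085,8.859,8.627,8.389,8.144,7.891,7.630,7.359,7.079,6.786,6.481,6.160,5.822,5.462,5.078,4.662,4.204,3.691,3.093,2.348,1.208,0.000,0.000,0.000
6250,10.971,10.784,10.595,10.402,10.205,10.004,9.800,9.590,9.377,9.158,8.934,8.704,8.468,8.225,7.975,7.716,7.449,7.172,6.883,6.582,6.267,5.935,5.583,5.207,4.802,4.359,3.866,3.301,2.616,1.669,0.000
6500,11.409,11.230,11.048,10.863,10.675,10.484,10.288,10.089,9.887,9.679,9.468,9.251,9.029,8.802,8.568,8.329,8.082,7.827,7.563,7.290,7.007,6.711,6.402,6.077,5.734,5.369,4.977,4.552,4.082,3.551,2.925
6750,11.848,11.676,11.501,11.323,11.143,10.960,10.773,10.583,10.390,10.193,9.992,9.787,9.578,9.364,9.145,8.920,8.690,8.454,8.210,7.960,7.701,7.433,7.155,6.866,6.564,6.247,5.914,5.561,5.183,4.776,4.331
7000,12.287,12.121,11.953,11.782,11.608,11.433,11.254,11.072,10.888,10.700,10.509,10.314,10.116,9.913,9.707,9.495,9.279,9.058,8.832,8.599,8.360,8.114,7.860,7.598,7.326,7.044,6.750,6.443,6.120,5.780,5.418
7250,12.726,12.566,12.403,12.239,12.072,11.903,11.731,11.557,11.381,11.201,11.019,10.833,10.644,10.452,10.256,10.057,9.853,9.645,9.433,9.215,8.993,8.764,8.530,8.289,8.041,7.784,7.520,7.245,6.960,6.662,6.350
7500,13.165,13.010,12.853,12.694,12.534,12.371,12.206,12.039,11.869,11.697,11.523,11.345,11.165,10.982,10.796,10.607,10.414,10.217,10.017,9.812,9.604,9.390,9.172,8.948,8.719,8.483,8.240,7.991,7.733,7.466,7.190
7750,13.604,13.454,13.302,13.149,12.994,12.837,12.678,12.517,12.354,12.189,12.022,11.852,11.679,11.505,11.327,11.147,10.963,10.777,10.587,10.394,10.197,9.996,9.791,9.582,9.368,9.149,8.925,8.695,8.458,8.215,7.965
8000,14.042,13.897,13.751,13.602,13.453,13.301,13.148,12.993,12.836,12.677,12.516,12.353,12.188,12.020,11.850,11.678,11.503,11.326,11.145,10.962,10.775,10.586,10.392,10.195,9.995,9.790,9.580,9.366,9.147,8.923,8.693
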