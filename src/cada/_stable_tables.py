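"""Quantiles of the standard alpha-stable law on an (alpha, beta) grid.

Values are x_p for p in (0.05, 0.25, 0.5, 0.75, 0.95) of the stable
distribution with unit dispersion and zero location in the continuous
(S0) parameterization, computed by numerical integration of the
characteristic function.  Negative skewness follows from the mirror
symmetry x_p(alpha, -beta) = -x_{1-p}(alpha, beta).
"""

import numpy as np

ALPHA_GRID = np.array([0.6 , 0.65, 0.7 , 0.75, 0.8 , 0.85, 0.9 , 0.95, 1.  , 1.05, 1.1 , 1.15, 1.2 ,
 1.25, 1.3 , 1.35, 1.4 , 1.45, 1.5 , 1.55, 1.6 , 1.65, 1.7 , 1.75, 1.8 , 1.85,
 1.9 , 1.95, 2.  ])

BETA_GRID = np.array([0.0, 0.25, 0.5, 0.75, 1.0])

PROBS = (0.05, 0.25, 0.5, 0.75, 0.95)

QUANTILES = np.array([[[-27.439819, -1.162104, 0.000000, 1.162104, 27.439819],
  [-15.960263, -0.638328, 0.077627, 1.983648, 41.409257],
  [-7.269473, -0.459041, 0.271981, 3.068799, 57.667687],
  [-1.908024, -0.394456, 0.580997, 4.395394, 76.066744],
  [-0.852328, -0.275553, 0.996638, 5.947299, 96.490397]],

 [[-20.682793, -1.121650, 0.000000, 1.121650, 20.682793],
  [-12.503004, -0.658199, 0.083879, 1.828189, 30.330468],
  [-6.046873, -0.485361, 0.267262, 2.740332, 41.281929],
  [-1.813156, -0.410659, 0.548809, 3.834390, 53.420047],
  [-0.905298, -0.292018, 0.919713, 5.093589, 66.655661]],

 [[-16.235162, -1.090064, 0.000000, 1.090064, 16.235162],
  [-10.149105, -0.677216, 0.088873, 1.705291, 23.227991],
  [-5.175553, -0.509769, 0.262060, 2.485138, 31.001298],
  [-1.746710, -0.426704, 0.519743, 3.406247, 39.467770],
  [-0.956503, -0.308932, 0.853269, 4.452489, 48.562583]],

 [[-13.163239, -1.065201, 0.000000, 1.065201, 13.163239],
  [-8.476398, -0.695381, 0.092716, 1.606093, 18.430950],
  [-4.532984, -0.532522, 0.256452, 2.281698, 24.183982],
  [-1.701463, -0.442692, 0.493147, 3.069803, 30.358285],
  [-1.006242, -0.326237, 0.794848, 3.955391, 36.907426]],

 [[-10.956246, -1.045535, 0.000000, 1.045535, 10.956246],
  [-7.245481, -0.712652, 0.095509, 1.524641, 15.049808],
  [-4.045905, -0.553854, 0.250487, 2.116014, 19.453960],
  [-1.672808, -0.458697, 0.468534, 2.798918, 24.121771],
  [-1.054781, -0.343894, 0.742705, 3.559571, 29.020023]],

 [[-9.317940, -1.029946, 0.000000, 1.029946, 9.317940],
  [-6.313099, -0.728973, 0.097345, 1.456801, 12.580702],
  [-3.668435, -0.573968, 0.244197, 1.978635, 16.046474],
  [-1.657829, -0.474775, 0.445530, 2.576311, 19.680707],
  [-1.102355, -0.361880, 0.695565, 3.237260, 23.459539]],

 [[-8.067902, -1.017583, 0.000000, 1.017583, 8.067902],
  [-5.589593, -0.744307, 0.098311, 1.399610, 10.723054],
  [-3.370710, -0.593043, 0.237596, 1.862971, 13.512859],
  [-1.654652, -0.490968, 0.423838, 2.390160, 16.411680],
  [-1.149177, -0.380185, 0.652470, 2.969747, 19.402278]],

 [[-7.091609, -1.007780, 0.000000, 1.007780, 7.091609],
  [-5.016672, -0.758650, 0.098490, 1.350891, 9.289530],
  [-3.132666, -0.611238, 0.230694, 1.764301, 11.577567],
  [-1.661494, -0.507312, 0.403220, 2.232137, 13.936512],
  [-1.195435, -0.398810, 0.612684, 2.744027, 16.353827]],

 [[-6.313752, -1.000000, 0.000000, 1.000000, 6.313752],
  [-4.555196, -0.772033, 0.097957, 1.309003, 8.158914],
  [-2.940461, -0.628686, 0.223492, 1.679156, 10.064629],
  [-1.675941, -0.523835, 0.383478, 2.096223, 12.016320],
  [-1.241305, -0.417765, 0.575630, 2.550816, 14.004804]],

 [[-5.683275, -0.993810, 0.000000, 0.993810, 5.683275],
  [-4.178147, -0.784521, 0.096785, 1.272683, 7.250200],
  [-2.784346, -0.645510, 0.215988, 1.604935, 8.857803],
  [-1.695544, -0.540566, 0.364445, 1.977971, 10.494846],
  [-1.286948, -0.437067, 0.540848, 2.383329, 12.154537]],

 [[-5.164646, -0.988852, 0.000000, 0.988852, 5.164646],
  [-3.866436, -0.796193, 0.095035, 1.240935, 6.507707],
  [-2.657341, -0.661812, 0.208179, 1.539647, 7.878016],
  [-1.718457, -0.557529, 0.345981, 1.874030, 9.266721],
  [-1.332519, -0.456741, 0.507961, 2.236505, 10.668728]],

 [[-4.732568, -0.984839, 0.000000, 0.984839, 4.732568],
  [-3.606311, -0.807136, 0.092767, 1.212962, 5.892217],
  [-2.554366, -0.677690, 0.200058, 1.481737, 7.070080],
  [-1.743481, -0.574750, 0.327960, 1.781824, 8.258976],
  [-1.378162, -0.476819, 0.476657, 2.106500, 9.455001]],

 [[-4.368675, -0.981537, 0.000000, 0.981537, 4.368675],
  [-3.387703, -0.817441, 0.090031, 1.188115, 5.375510],
  [-2.471627, -0.693225, 0.191620, 1.429976, 6.394595],
  [-1.769893, -0.592257, 0.310271, 1.699346, 7.419875],
  [-1.424021, -0.497340, 0.446671, 1.990343, 8.448260]],

 [[-4.059419, -0.978764, 0.000000, 0.978764, 4.059419],
  [-3.203144, -0.827195, 0.086870, 1.165857, 4.936902],
  [-2.406121, -0.708498, 0.182858, 1.383368, 5.822869],
  [-1.797274, -0.610078, 0.292816, 1.625004, 6.711967],
  [-1.470236, -0.518348, 0.417777, 1.885707, 7.601631]],

 [[-3.794667, -0.976379, 0.000000, 0.976379, 3.794667],
  [-3.047025, -0.836479, 0.083321, 1.145743, 4.560992],
  [-2.355254, -0.723579, 0.173764, 1.341102, 5.333646],
  [-1.825398, -0.628247, 0.275502, 1.557519, 6.107642],
  [-1.516948, -0.539897, 0.389775, 1.790739, 6.880715]],

 [[-3.566762, -0.974273, 0.000000, 0.974273, 3.566762],
  [-2.915055, -0.845371, 0.079416, 1.127397, 4.236164],
  [-2.316646, -0.738536, 0.164328, 1.302501, 4.910941],
  [-1.854161, -0.646798, 0.258243, 1.495846, 5.586211],
  [-1.564302, -0.562045, 0.362484, 1.703950, 6.259830]],

 [[-3.369861, -0.972367, 0.000000, 0.972367, 3.369861],
  [-2.803844, -0.853942, 0.075179, 1.110505, 3.953565],
  [-2.288128, -0.753435, 0.154540, 1.266997, 4.542587],
  [-1.883539, -0.665773, 0.240960, 1.439123, 5.131958],
  [-1.612447, -0.584860, 0.335742, 1.624124, 5.719518]],

 [[-3.199445, -0.970602, 0.000000, 0.970602, 3.199445],
  [-2.710563, -0.862259, 0.070629, 1.094801, 3.706399],
  [-2.267823, -0.768340, 0.144387, 1.234106, 4.219235],
  [-1.913560, -0.685218, 0.223571, 1.386625, 4.732811],
  [-1.661539, -0.608420, 0.309393, 1.550257, 5.244846]],

 [[-3.051941, -0.968933, 0.000000, 0.968933, 3.051941],
  [-2.632721, -0.870385, 0.065780, 1.080061, 3.489409],
  [-2.254186, -0.783314, 0.133853, 1.203411, 3.933659],
  [-1.944294, -0.705188, 0.206001, 1.337736, 4.379420],
  [-1.711745, -0.632812, 0.283289, 1.481512, 4.824236]],

 [[-2.924407, -0.967331, 0.000000, 0.967331, 2.924407],
  [-2.568062, -0.878379, 0.060640, 1.066095, 3.298482],
  [-2.246005, -0.798422, 0.122917, 1.174548, 3.680248],
  [-1.975839, -0.725744, 0.188170, 1.291925, 4.064508],
  [-1.763243, -0.658136, 0.257286, 1.417179, 4.448656]],

 [[-2.814293, -0.965774, 0.000000, 0.965774, 2.814293],
  [-2.514548, -0.886297, 0.055212, 1.052740, 3.130332],
  [-2.242356, -0.813732, 0.111556, 1.147201, 3.454629],
  [-2.008320, -0.746956, 0.169997, 1.248726, 3.782417],
  [-1.816230, -0.684504, 0.231236, 1.356646, 4.111047]],

 [[-2.719297, -0.964246, 0.000000, 0.964246, 2.719297],
  [-2.470394, -0.894196, 0.049495, 1.039857, 2.982216],
  [-2.242554, -0.829317, 0.099739, 1.121088, 3.253357],
  [-2.041888, -0.768907, 0.151397, 1.207725, 3.528751],
  [-1.870920, -0.712047, 0.204987, 1.299382, 3.805921]],

 [[-2.637307, -0.962738, 0.000000, 0.962738, 2.637307],
  [-2.434084, -0.902129, 0.043481, 1.027323, 2.851733],
  [-2.246105, -0.845252, 0.087431, 1.095956, 3.073637],
  [-2.076717, -0.791693, 0.132278, 1.168551, 3.300104],
  [-1.927551, -0.740914, 0.178381, 1.244912, 3.529066]],

 [[-2.566404, -0.961243, 0.000000, 0.961243, 2.566404],
  [-2.404367, -0.910155, 0.037158, 1.015030, 2.736680],
  [-2.252664, -0.861623, 0.074587, 1.071576, 2.913091],
  [-2.113012, -0.815427, 0.112541, 1.130860, 3.093796],
  [-1.986393, -0.771276, 0.151244, 1.192802, 3.277314]],

 [[-2.504881, -0.959756, 0.000000, 0.959756, 2.504881],
  [-2.380234, -0.918330, 0.030507, 1.002879, 2.634996],
  [-2.262011, -0.878526, 0.061154, 1.047737, 2.769567],
  [-2.151006, -0.840239, 0.092072, 1.094335, 2.907625],
  [-2.047749, -0.803334, 0.123387, 1.142651, 3.048305]],

 [[-2.451257, -0.958277, 0.000000, 0.958277, 2.451257],
  [-2.360890, -0.926717, 0.023503, 0.990777, 2.544766],
  [-2.274026, -0.896067, 0.047066, 1.024239, 2.641027],
  [-2.190973, -0.866285, 0.070745, 1.058670, 2.739642],
  [-2.111967, -0.837320, 0.094597, 1.094071, 2.840228]],

 [[-2.404272, -0.956803, 0.000000, 0.956803, 2.404272],
  [-2.345720, -0.935384, 0.016114, 0.978636, 2.464237],
  [-2.288677, -0.914371, 0.032245, 1.000890, 2.525510],
  [-2.233230, -0.893751, 0.048412, 1.023570, 2.587983],
  [-2.179451, -0.873511, 0.064632, 1.046680, 2.651546]],

 [[-2.362870, -0.955335, 0.000000, 0.955335, 2.362870],
  [-2.334260, -0.944408, 0.008297, 0.966365, 2.391835],
  [-2.306017, -0.933582, 0.016596, 0.977500, 2.421144],
  [-2.278150, -0.922858, 0.024899, 0.988739, 2.450784],
  [-2.250669, -0.912232, 0.033209, 1.000085, 2.480744]],

 [[-2.326174, -0.953873, 0.000000, 0.953873, 2.326174],
  [-2.326174, -0.953873, 0.000000, 0.953873, 2.326174],
  [-2.326174, -0.953873, 0.000000, 0.953873, 2.326174],
  [-2.326174, -0.953873, 0.000000, 0.953873, 2.326174],
  [-2.326174, -0.953873, 0.000000, 0.953873, 2.326174]]])
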