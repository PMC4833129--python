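roi,da_mean,da_std,dr_mean,dr_std,md_mean,md_std,fa_mean,fa_std,po_mean,po_std,odi_mean,odi_std,icvf_mean,icvf_std,fiso_mean,fiso_std
ACR-L,840,40,392,4,541,36,0.470,0.033,0.463,0.042,0.292,0.023,0.655,0.057,0.149,0.033
ACR-R,848,37,395,4,546,34,0.467,0.035,0.457,0.039,0.285,0.024,0.656,0.055,0.160,0.029
ALIC-L,858,45,316,3,497,29,0.556,0.038,0.473,0.038,0.266,0.031,0.676,0.050,0.111,0.022
ALIC-R,876,51,322,3,506,32,0.556,0.037,0.461,0.038,0.260,0.026,0.682,0.053,0.124,0.025
BCC,1184,64,380,8,648,70,0.628,0.054,0.510,0.056,0.141,0.016,0.712,0.038,0.230,0.047
CGC-L,872,41,348,2,522,23,0.521,0.028,0.468,0.036,0.242,0.026,0.608,0.046,0.090,0.027
CGC-R,844,39,369,2,527,21,0.485,0.032,0.443,0.035,0.265,0.030,0.581,0.048,0.085,0.026
CGH-L,855,54,469,5,598,45,0.388,0.031,0.322,0.026,0.344,0.027,0.502,0.045,0.112,0.050
CGH-R,852,44,442,3,579,32,0.412,0.031,0.338,0.026,0.337,0.025,0.507,0.043,0.094,0.041
CP-L,1007,57,269,3,515,38,0.682,0.038,0.621,0.073,0.190,0.017,0.768,0.041,0.148,0.027
CP-R,1049,63,293,5,545,48,0.671,0.043,0.590,0.067,0.187,0.017,0.775,0.042,0.171,0.031
CST-L,883,83,332,7,516,72,0.584,0.042,0.686,0.134,0.208,0.019,0.769,0.053,0.181,0.049
CST-R,887,85,333,7,517,68,0.587,0.040,0.685,0.144,0.208,0.023,0.772,0.053,0.184,0.047
EC-L,835,45,399,5,544,44,0.455,0.034,0.379,0.033,0.320,0.026,0.531,0.037,0.075,0.037
EC-R,844,39,410,4,555,35,0.444,0.031,0.364,0.028,0.317,0.021,0.528,0.034,0.087,0.032
Fx,1716,141,830,16,1126,153,0.477,0.055,0.231,0.050,0.168,0.033,0.770,0.077,0.622,0.091
Fx-ST-L,1025,73,448,7,641,71,0.510,0.040,0.386,0.057,0.236,0.020,0.593,0.045,0.214,0.065
Fx-ST-R,1092,73,500,7,697,68,0.486,0.038,0.347,0.051,0.244,0.024,0.579,0.042,0.262,0.063
GCC,1325,93,530,8,795,83,0.575,0.033,0.411,0.045,0.180,0.018,0.722,0.047,0.336,0.054
ICP-L,817,46,340,3,499,27,0.526,0.038,0.569,0.032,0.248,0.028,0.683,0.038,0.125,0.039
ICP-R,810,46,322,3,484,27,0.539,0.039,0.590,0.037,0.247,0.030,0.683,0.038,0.105,0.032
MCP,921,90,362,6,549,66,0.569,0.045,0.662,0.107,0.220,0.028,0.809,0.050,0.204,0.045
ML-L,884,64,288,3,487,22,0.615,0.048,0.575,0.035,0.180,0.024,0.642,0.029,0.097,0.028
ML-R,900,75,287,2,491,24,0.625,0.047,0.571,0.031,0.175,0.023,0.638,0.031,0.096,0.031
PCR-L,863,79,397,6,552,65,0.494,0.032,0.530,0.049,0.224,0.016,0.628,0.053,0.117,0.046
PCR-R,847,55,378,4,534,44,0.503,0.029,0.528,0.044,0.230,0.017,0.616,0.048,0.101,0.033
PCT,767,44,328,3,474,25,0.514,0.036,0.598,0.032,0.254,0.026,0.713,0.043,0.102,0.034
PLIC-L,860,32,259,2,460,22,0.643,0.027,0.646,0.032,0.209,0.018,0.743,0.036,0.105,0.020
PLIC-R,875,35,264,2,468,23,0.640,0.027,0.629,0.027,0.205,0.016,0.736,0.033,0.111,0.021
PTR-L,1072,99,418,9,636,89,0.580,0.038,0.488,0.051,0.161,0.022,0.634,0.053,0.191,0.064
PTR-R,962,64,332,5,542,48,0.608,0.036,0.548,0.063,0.180,0.022,0.656,0.057,0.132,0.035
RLIC-L,904,54,318,4,513,37,0.600,0.031,0.556,0.040,0.199,0.021,0.686,0.038,0.129,0.032
RLIC-R,905,44,328,3,520,29,0.588,0.030,0.540,0.037,0.211,0.019,0.681,0.040,0.135,0.031
SCC,1102,42,236,3,525,30,0.749,0.027,0.666,0.042,0.122,0.013,0.764,0.038,0.125,0.027
SCP-L,1316,106,534,8,795,82,0.579,0.033,0.454,0.036,0.154,0.026,0.724,0.041,0.329,0.057
SCP-R,1243,91,457,5,719,58,0.607,0.031,0.490,0.029,0.145,0.024,0.718,0.039,0.295,0.048
SCR-L,760,35,337,3,478,30,0.501,0.030,0.595,0.039,0.268,0.016,0.689,0.044,0.103,0.024
SCR-R,760,29,344,2,483,22,0.488,0.025,0.586,0.033,0.273,0.018,0.692,0.041,0.114,0.026
SFO-L,812,73,361,6,511,64,0.500,0.038,0.499,0.057,0.286,0.029,0.661,0.061,0.117,0.047
SFO-R,810,49,361,4,510,35,0.491,0.037,0.483,0.045,0.282,0.032,0.645,0.069,0.112,0.038
SLF-L,745,30,332,2,470,23,0.494,0.025,0.605,0.036,0.269,0.018,0.699,0.040,0.096,0.021
SLF-R,763,29,344,2,484,20,0.489,0.023,0.571,0.035,0.275,0.020,0.693,0.042,0.107,0.025
SS-L,967,73,419,5,602,52,0.511,0.029,0.427,0.037,0.225,0.026,0.594,0.041,0.172,0.047
SS-R,951,57,387,3,575,36,0.536,0.028,0.447,0.039,0.237,0.028,0.635,0.049,0.167,0.032
TAP-L,2053,266,1328,25,1569,251,0.329,0.048,0.157,0.055,0.179,0.042,0.819,0.079,0.758,0.118
TAP-R,1788,190,1026,17,1280,176,0.414,0.054,0.230,0.064,0.143,0.028,0.759,0.089,0.624,0.123
UNC-L,864,66,438,6,580,56,0.419,0.048,0.329,0.037,0.306,0.052,0.455,0.033,0.061,0.047
UNC-R,926,76,464,8,618,72,0.425,0.055,0.303,0.045,0.296,0.053,0.474,0.054,0.116,0.103
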