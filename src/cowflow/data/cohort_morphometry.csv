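label,length_sc1_mean_cm,length_sc1_sd_cm,radius_sc1_mean_cm,radius_sc1_sd_cm,length_sc2_mean_cm,length_sc2_sd_cm,radius_sc2_mean_cm,radius_sc2_sd_cm
R ICA G1,5.26,0.69,0.24,0.02,5.2,0.62,0.24,0.02
L ICA G1,5.48,0.86,0.24,0.02,5.48,0.6,0.25,0.02
R ICA G2,0.88,0.17,0.2,0.02,0.98,0.24,0.2,0.03
L ICA G2,0.91,0.18,0.21,0.02,0.93,0.2,0.21,0.03
R ICA G3,0.65,0.09,0.21,0.02,0.63,0.13,0.2,0.03
L ICA G3,0.62,0.18,0.23,0.05,0.64,0.18,0.21,0.02
R OA,0.82,0.28,0.09,0.03,0.72,0.28,0.09,0.03
L OA,0.57,0.07,0.09,0.02,0.74,0.29,0.09,0.02
BA,3.04,0.25,0.17,0.01,3.1,0.42,0.16,0.02
R MCA G1,2.27,0.81,0.16,0.01,2.32,0.8,0.15,0.01
L MCA G1,2.51,0.86,0.17,0.02,2.54,0.76,0.16,0.01
R MCA G2,2.93,0.76,0.1,0.02,3.07,0.86,0.08,0.01
L MCA G2,2.61,0.77,0.1,0.01,2.72,0.92,0.09,0.01
R MCA G3,1.44,0.3,0.07,0.01,1.4,0.23,0.06,0.01
L MCA G3,1.48,0.41,0.07,0.01,1.5,0.38,0.06,0.01
R PCA G1,0.87,0.18,0.13,0.03,0.9,0.18,0.11,0.03
L PCA G1,0.87,0.18,0.11,0.03,0.88,0.17,0.11,0.03
R PCA G2,2.57,0.37,0.11,0.01,2.63,0.42,0.09,0.01
L PCA G2,2.8,0.37,0.11,0.01,2.88,0.36,0.1,0.01
R PCA G3,1.46,0.32,0.08,0.02,1.56,0.21,0.07,0.01
L PCA G3,1.35,0.2,0.08,0.01,1.34,0.12,0.07,0.02
R PCoA,1.46,0.2,0.07,0.02,1.53,0.21,0.07,0.03
L PCoA,1.49,0.22,0.08,0.03,1.53,0.15,0.07,0.04
ACoA,0.31,0.12,0.14,0.07,0.34,0.13,0.12,0.07
R ACA G1,2.17,0.87,0.12,0.03,2.16,0.89,0.1,0.03
L ACA G1,1.89,0.84,0.12,0.02,1.97,0.84,0.11,0.02
R ACA G2,3.66,0.76,0.1,0.01,3.39,0.26,0.09,0.02
L ACA G2,3.59,0.6,0.1,0.01,3.61,0.47,0.09,0.01
R ACA G3,1.08,0.19,0.08,0.01,0.86,0.29,0.07,0.02
L ACA G3,1.19,0.37,0.08,0.02,0.83,0.16,0.07,0.01
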