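vessels,h_cm,E_Pa,beta_Pa_cm,P0_mmHg,Rt_Pa_s_per_cm3,Ct_cm3_per_Pa
R/L ICA G1-G3,0.05,890000.0,4529.48,100.0,,
R/L MCA G1-G2,0.036,1600000.0,136122.4,90.0,,
R/L MCA G3,0.036,1600000.0,136122.4,90.0,10025.8144,2.1e-07
R/L OA,0.009375,1600000.0,35448.55,100.0,26771.0576,3e-08
R/L ACA G1-G2,0.03,1600000.0,113435.4,90.0,,
R/L ACA G3,0.03,1600000.0,113435.4,90.0,10732.421,3.53e-07
R/L PCoA,0.018,1600000.0,68061.22,90.0,,
BA,0.04,1600000.0,151247.2,100.0,,
ACoA,0.019,1600000.0,71842.4,90.0,,
R/L PCA G1-G2,0.027,1600000.0,102091.8,90.0,,
R/L PCA G3,0.027,1600000.0,102091.8,90.0,10732.421,4.35e-07
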