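acronym,name,units,mc_mean,mc_sd,mp_mean,mp_sd,fc_mean,fc_sd,fp_mean,fp_sd,p_disease,p_gender,p_interaction,p_t_male,p_t_female
MFH,Morphological face height,mm,122.15,7.79,136.57,7.26,113.78,4.30,122.53,6.34,1.93E-11,4.00E-10,7.21E-02,6.48E-08,1.01E-04
LFH,Lower facial height,mm,71.14,6.19,82.39,5.33,65.23,3.46,74.69,5.63,6.95E-13,4.86E-07,4.70E-01,4.79E-08,5.79E-06
FB,Face breadth,mm,127.66,7.80,144.54,7.07,125.38,6.41,130.31,9.77,2.40E-09,1.67E-05,1.34E-03,1.20E-09,1.04E-01
BB,Bigonial breadth,mm,136.90,8.52,140.19,9.36,128.90,6.62,128.87,7.81,3.09E-01,2.97E-06,3.88E-01,2.20E-01,9.90E-01
BtW,Bitragal width,mm,155.03,6.11,165.73,7.91,147.34,4.79,149.51,4.89,2.73E-06,3.60E-12,4.09E-03,7.02E-06,2.16E-01
BnW,Binocular width,mm,93.60,4.10,100.22,4.77,87.88,2.96,91.63,5.44,6.48E-07,8.59E-10,1.63E-01,8.54E-06,2.34E-02
ICW,Intercanthal width,mm,41.56,2.73,42.21,2.96,38.10,1.90,38.54,3.04,3.63E-01,2.51E-07,8.59E-01,4.39E-01,6.33E-01
OW,Ocular width,mm,26.62,1.77,29.38,1.81,25.46,1.29,27.05,1.78,9.15E-08,2.97E-05,1.39E-01,4.51E-06,7.48E-03
NH,Nose height,mm,52.89,3.58,57.17,3.77,50.09,2.22,50.34,4.68,2.29E-03,2.26E-07,1.96E-02,2.79E-04,8.50E-01
NL,Nose length,mm,45.35,3.22,50.97,4.75,41.65,2.57,42.06,4.41,1.68E-04,7.58E-10,4.65E-03,3.26E-05,7.52E-01
NW,Nose width,mm,43.24,2.30,51.21,4.14,40.21,2.50,45.59,2.25,1.01E-15,2.09E-08,6.48E-02,1.92E-09,4.86E-07
ND,Nasal depth,mm,19.14,1.87,21.19,2.40,18.60,1.82,19.56,2.33,1.31E-03,2.99E-02,2.68E-01,2.34E-03,2.02E-01
MW,Mouth width,mm,49.49,3.21,56.39,3.94,47.84,3.34,53.50,4.55,1.11E-10,1.05E-02,4.76E-01,7.11E-08,4.20E-04
TULH,Total upper lip height,mm,24.89,2.79,28.64,3.12,22.47,1.54,26.97,3.36,1.57E-08,2.37E-03,5.65E-01,9.47E-05,8.14E-05
PL,Philtrum length,mm,17.86,2.34,19.40,3.51,15.94,1.53,18.24,3.45,5.47E-03,2.21E-02,5.69E-01,8.72E-02,2.40E-02
UVH,Upper vermilion height,mm,9.50,1.97,11.80,2.30,8.25,0.90,10.95,1.09,3.61E-08,1.22E-02,6.38E-01,7.01E-04,2.18E-08
LVH,Lower vermilion height,mm,8.85,1.81,13.50,2.29,8.28,0.99,11.53,1.91,9.95E-15,4.08E-03,1.06E-01,1.85E-09,4.20E-06
UVCL,Upper vermilion curve length,mm,10.17,2.34,12.95,2.84,8.69,0.96,12.07,1.41,2.63E-08,1.93E-02,5.46E-01,7.66E-04,1.83E-08
LVCL,Lower vermilion curve length,mm,9.48,2.22,15.18,3.16,8.75,1.25,12.76,2.66,2.58E-13,7.44E-03,1.43E-01,1.53E-08,1.92E-05
MCL,Mandible curve length,mm,73.81,7.19,87.38,8.05,72.35,4.08,82.51,8.45,1.62E-10,6.19E-02,3.09E-01,3.17E-07,2.80E-04
FLI,Facial length index,index,95.87,6.44,94.60,4.83,90.97,5.89,94.53,8.55,6.25E-01,9.69E-02,1.06E-01,4.55E-01,1.82E-01
MFI,Mandibulo facial index,index,107.37,5.44,97.13,6.88,103.01,6.87,99.24,7.05,2.17E-06,4.56E-01,3.44E-02,1.50E-06,1.36E-01
II,Intercanthal index,index,44.41,2.39,42.12,2.20,43.37,1.77,42.04,1.82,1.68E-04,2.52E-01,3.24E-01,1.54E-03,4.55E-02
NLI,Nasal length index,index,43.35,2.44,41.88,1.96,44.04,1.73,41.09,3.39,2.97E-04,9.32E-01,1.89E-01,2.90E-02,5.18E-03
NWI,Nasal width index,index,82.11,6.91,89.76,7.30,80.46,6.66,91.40,10.70,3.21E-06,9.98E-01,3.68E-01,6.90E-04,1.89E-03
LI,Labial index,index,33.74,7.22,41.51,7.80,32.08,4.97,39.30,5.37,3.81E-06,2.12E-01,8.60E-01,1.07E-03,4.46E-04
ULLI,Upper lip length index,index,34.97,2.08,34.30,3.22,34.48,1.99,36.06,2.79,6.64E-01,2.93E-01,6.40E-02,4.10E-01,7.56E-02
LLLI,Lower lip length index,index,27.01,3.38,28.27,2.96,27.13,1.76,28.35,3.70,7.81E-02,8.93E-01,9.75E-01,1.86E-01,2.49E-01
CHI,Chin height index,index,39.29,3.33,38.32,3.42,38.54,2.68,36.79,4.46,1.09E-01,1.61E-01,6.32E-01,3.36E-01,1.92E-01
ICI,Iridio chelial index,index,107.57,8.76,104.97,7.85,103.67,7.60,99.64,9.15,9.65E-02,1.88E-02,7.13E-01,2.95E-01,1.86E-01
EAI,Endocanthal alar index,index,96.27,7.08,82.84,7.73,95.14,8.04,84.70,7.45,5.35E-10,8.35E-01,3.92E-01,2.10E-07,6.41E-04
ACI,Alar chelial index,index,87.71,7.09,91.10,8.34,84.18,4.17,85.68,6.97,1.04E-01,6.93E-03,5.60E-01,1.46E-01,4.68E-01
LOTI,Labio orbital triangle index,index,104.95,5.29,107.97,7.33,104.01,3.10,107.65,5.35,1.27E-02,6.30E-01,8.13E-01,1.17E-01,2.72E-02
NOT,Naso orbital triangle,index,81.80,3.72,82.29,4.39,81.55,2.17,84.48,3.28,7.18E-02,2.47E-01,1.45E-01,6.87E-01,6.15E-03
NCT,Naso chelial triangle,index,80.89,5.61,80.86,7.80,83.66,4.27,81.78,7.01,5.91E-01,2.16E-01,5.34E-01,9.89E-01,3.70E-01
SoD,Supraorbital depth,mm,129.22,3.88,135.74,6.06,120.20,4.26,122.25,4.77,6.03E-05,1.84E-15,5.00E-02,1.02E-04,2.08E-01
UFD,Upper facial depth,mm,124.76,3.40,130.34,5.38,116.44,4.29,117.69,4.17,2.70E-04,4.47E-16,3.57E-02,1.57E-04,4.09E-01
OTD,Orbito tragial depth,mm,89.25,4.64,93.61,5.09,83.13,4.46,85.44,5.57,2.39E-03,2.09E-08,3.68E-01,3.96E-03,2.07E-01
LTD,Labio tragial depth,mm,120.05,4.83,128.46,7.17,108.38,4.50,114.43,6.17,2.96E-07,1.39E-14,3.83E-01,3.59E-05,3.71E-03
MFD,Middle facial depth,mm,132.90,3.94,142.17,7.05,123.86,4.95,127.73,4.54,1.38E-07,1.57E-14,3.12E-02,3.67E-06,2.86E-02
SD,Sublabial depth,mm,145.27,5.01,156.92,9.01,134.34,5.48,141.91,6.23,7.49E-09,2.90E-12,1.94E-01,4.78E-06,1.01E-03
LFD,Lower facial depth,mm,155.61,6.06,169.90,9.38,145.18,6.87,152.94,7.47,3.12E-09,2.91E-11,6.67E-02,3.89E-07,4.68E-03
GTD,Gonion tragial distance,mm,61.06,6.70,73.69,13.28,58.86,5.59,61.33,6.09,7.71E-05,6.84E-04,1.56E-02,2.79E-04,2.42E-01
GGD,Gonion gnathion distance,mm,112.00,7.24,117.84,7.90,103.88,6.89,110.27,6.60,4.22E-04,1.16E-05,8.69E-01,1.23E-02,1.19E-02
LSEPD,Labiale superius Esthetic plane distance,mm,-0.30,2.12,-1.09,2.23,-1.75,1.69,0.88,2.90,2.33E-01,6.21E-01,1.60E-03,2.30E-01,4.52E-03
LIEPD,Labiale inferius Esthetic plane distance,mm,0.74,2.85,2.26,2.58,-0.88,2.42,3.38,3.76,1.41E-04,7.10E-01,4.49E-02,6.42E-02,7.92E-04
LIE_LSE,Labiale inferius to E distance minus Labiale superius to E distance,mm,1.04,1.52,3.35,2.25,0.88,1.20,2.50,2.66,2.31E-05,2.68E-01,4.58E-01,2.24E-04,3.71E-02
GTVLD,Glabella TVL distance,mm,-2.00,2.69,-2.52,3.79,-1.48,2.13,-4.81,3.73,2.29E-02,2.30E-01,5.97E-02,5.90E-01,4.90E-03
PrTVLD,Pronasale TVL distance,mm,14.99,1.44,17.67,2.20,14.02,1.67,14.04,2.17,3.90E-04,1.18E-06,3.15E-03,1.88E-05,9.73E-01
PoTVLD,Pogonion TVL distance,mm,-8.45,3.82,-10.96,6.15,-2.32,4.37,5.79,6.57,7.23E-02,6.07E-01,7.51E-01,1.05E-01,3.88E-01
NFrA,Nasofrontal angle,degree,144.00,6.74,132.65,9.10,148.06,5.12,141.75,5.67,1.54E-07,1.28E-04,1.26E-01,2.14E-05,2.49E-03
NmA,Nasomental angle,degree,134.61,5.21,130.17,4.03,134.75,3.91,130.69,5.61,1.50E-04,7.64E-01,8.65E-01,2.44E-03,2.48E-02
NFA,Naso facial angle,degree,28.17,3.64,32.13,2.67,27.94,2.49,32.31,3.66,1.84E-07,9.70E-01,7.75E-01,1.41E-04,5.20E-04
CLA,Columella labial angle,degree,97.91,7.85,90.09,11.91,103.63,6.23,101.44,8.60,9.41E-03,1.21E-04,1.84E-01,1.22E-02,4.17E-01
FA,Facial angle,degree,169.22,4.75,168.39,5.66,168.44,4.63,166.19,6.39,2.50E-01,2.32E-01,5.67E-01,5.95E-01,2.64E-01
PTGP,Pass transglabellar plane,mm,283.45,9.79,310.76,11.12,266.42,17.92,269.33,12.74,7.29E-08,2.88E-15,8.85E-05,2.94E-11,6.01E-01
PMFP,Pass midfacial plane,mm,288.68,10.24,314.04,10.58,270.35,12.83,278.98,11.50,2.51E-10,4.15E-16,1.72E-03,1.73E-10,5.42E-02
PTNP,Pass transverse nasal plane,mm,293.61,15.12,316.81,15.14,286.32,16.34,292.29,15.13,1.52E-05,2.55E-05,1.74E-02,4.96E-06,2.92E-01
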