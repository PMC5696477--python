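conformer,e_rel,hb_backbone,hb_side,type,pop@98,pop@298,pop@450
yg1,0.000,N_PB_H···N_1;O_T_H···OC_PB,N_1_H···π,A1-γ_D(F)-g+/+,100,11.42,3.05
yg2,0.523,N_PB_H···N_1;O_T_H···OC_PB,O_S_H···OC_T,A2-γ_D(F)-g+/+,,,
yg3,0.786,N_PB_H···N_1;O_T_H···OC_PB,N_1_H···π,A1-γ_D(F)-g+/−,,4.25,1.72
yg4,0.973,N_PB_H···N_1;O_T_H···OC_PB,N_1_H···π,A1-γ_L(F)-g+/+,,3.18,1.56
yg5,1.121,N_PB_H···N_1;O_T_H···OC_PB,N_1_H···π,A1-γ_L(F)-g+/−,,2.98,1.57
yg6,1.230,N_1_H···OC_PB;O_T_H···OC_PB,O_S_H···OC_T,B-γ_L(F)-a/−,,,
yg7,1.779,N_PB_H···N_1;O_T_H···OC_PB,N_1_H···π,A2-γ_D(F)-g−/−,,3.17,2.34
yg8,1.783,N_PB_H···N_1;O_T_H···OC_PB,N_1_H···π,A2-γ_D(F)-g−/+,,3.54,2.53
yg9,1.819,N_PB_H···N_1;O_T_H···OC_PB,N_1_H···π,A2-γ_L(F)-g−/−,,1.59,1.24
yg10,1.843,N_PB_H···N_1;O_T_H···OC_PB,N_1_H···π,A2-γ_L(F)-g−/+,,2.01,1.55
yg11,1.858,N_PB_H···N_1;O_T_H···OC_PB,,A2-γ_L(F)-g+/+,,2.03,1.45
yg12,1.880,N_PB_H···N_1,N_1_H···π,A1-ε_D(E)-g+/+,,2.25,1.88
yg13,2.001,N_PB_H···N_1;O_T_H···OC_PB,,A2-γ_L(F)-g+/−,,1.35,1.07
yg14,2.011,N_PB_H···N_1,N_1_H···π,A1-β(E)-g+/+,,11.62,8.65
yg17,2.113,N_PB_H···N_1,N_1_H···π,A1-β(E)-g+/−,,10.57,8.10
yg18,2.360,N_PB_H···N_1,N_1_H···π,A1-ε_D(E)-g+/−,,1.02,1.10
yg19,2.375,N_PB_H···N_1,N_1_H···π,A1-ε_L(E)-g+/+,,1.49,1.58
yg25,2.552,N_PB_H···N_1,N_1_H···π,A1-ε_L(E)-g+/−,,1.33,1.55
yg26,2.613,N_PB_H···N_1,N_1_H···π,A2-ε_D(E)-g−/+,,3.37,3.72
yg27,2.619,N_PB_H···N_1,N_1_H···π,A2-ε_D(E)-g−/−,,3.91,4.44
yg29,2.710,N_PB_H···N_1;O_T_H···OC_PB,N_1_H···π,A1-γ_D(F)-g−/+,,,1.00
yg30,2.721,N_PB_H···N_1;O_T_H···OC_PB,N_1_H···π,A1-γ_D(F)-g−/−,,,1.00
yg31,2.723,N_PB_H···N_1,N_1_H···π,A2-β(E)-g−/+,,4.35,4.99
yg32,2.725,N_PB_H···N_1,N_1_H···π,A2-β(E)-g−/−,,2.75,3.23
yg33,2.744,N_PB_H···N_1,N_1_H···π,A2-ε_L(E)-g−/−,,2.18,2.87
yg35,2.777,N_PB_H···N_1,N_1_H···π,A2-ε_L(E)-g−/+,,3.07,3.93
yg38,2.905,N_PB_H···N_1;O_T_H···OC_PB,N_1_H···π,A1-γ_L(F)-g−/+,,,1.15
yg51,3.489,N_PB_H···N_1,N_1_H···π,A1-ε_D(E)-g−/−,,1.17,2.02
yg52,3.493,N_PB_H···N_1,N_1_H···π,A1-ε_D(E)-g−/+,,1.17,2.07
yg56,3.607,N_PB_H···N_1,N_1_H···π,A1-β(E)-g−/−,,,1.56
yg57,3.638,N_PB_H···N_1,N_1_H···π,A1-β(E)-g−/+,,,1.51
yg58,3.650,N_PB_H···N_1,,A2-ε_L(E)-g+/+,,1.00,1.90
yg63,3.900,N_PB_H···N_1,N_1_H···π,A1-ε_L(E)-g−/−,,,1.53
yg67,3.958,N_PB_H···N_1,N_1_H···π,A1-ε_L(E)-g−/+,,,1.66
yg71,4.183,N_PB_H···N_1,N_1_H···π,A2-α_L(E)-g−/−,,,1.29
yg72,4.214,N_PB_H···N_1,N_1_H···π,A2-α_L(E)-g−/+,,,1.04
yg100,5.416,N_1_H···OC_PB,N_1_H···π,B-β(E)-g−/−,,,1.15
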