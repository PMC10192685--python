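chemical,classification,concordance,hitc_met_neg,hitc_met_pos,max_med_met_neg,max_med_met_pos,bmd_met_neg,bmd_met_pos
Daidzein,Agonist,1,1.00,1.00,4.57,5.78,0.22,0.41
Resveratrol,Agonist,1,1.00,1.00,3.22,4.32,4.54,9.12
Atrazine,Agonist Negative,0,1.00,1.00,0.77,0.56,101.02,113.58
Spironolactone,Agonist Negative,1,0.00,0.66,0.43,0.23,>200,NA
"1,3-Diphenyl-1,3-propanedione",Bioactivated,1,1.00,1.00,1.64,3.45,4.39,4.86
2-Nitrobenzenamine,Bioactivated,0,0.00,0.00,0.10,0.08,>200,>200
4-Nonylphenol,Bioactivated,1,1.00,0.99,0.68,0.81,2.88,2.63
Azobenzene,Bioactivated,1,1.00,1.00,1.05,3.41,27.10,29.79
Biphenyl,Bioactivated,1,0.07,1.00,0.56,0.62,>200,116.90
Butralin,Bioactivated,1,1.00,1.00,0.83,2.13,9.11,7.56
Dimethylbenzylcarbinyl acetate,Bioactivated,0,1.00,1.00,1.04,1.11,58.23,107.96
Dodecylphenol,Bioactivated,1,1.00,1.00,1.43,1.78,0.90,0.45
Methoxychlor,Bioactivated,1,1.00,1.00,0.99,1.66,1.28,1.02
Phenolphthalin,Bioactivated,0,1.00,1.00,1.52,1.90,44.02,56.39
Pyriproxyfen,Bioactivated,1,0.42,1.00,1.13,1.73,NA,6.76
Quercetin,Bioactivated,1,1.00,1.00,1.72,2.32,22.22,11.61
(Z)-Nerol,Bioinactivated,0,1.00,1.00,0.48,0.54,135.87,71.00
"2,6-Dinitrotoluene",Bioinactivated,0,1.00,1.00,0.77,1.08,79.95,58.34
Benzyl salicylate,Bioinactivated,1,1.00,0.04,1.70,0.53,12.06,NA
Butylparaben,Bioinactivated,1,1.00,0.88,4.92,0.38,3.14,180.06
Carbofuran,Bioinactivated,1,1.00,1.00,1.27,0.62,19.12,118.90
Dehydroepiandrosterone,Bioinactivated,0,1.00,1.00,2.48,2.52,0.20,0.23
Penoxsulam,Bioinactivated,0,0.00,0.00,0.04,0.04,>200,>200
Pentaerythritol dibromide,Bioinactivated,1,1.00,1.00,1.81,1.36,12.08,24.29
Picloram,Bioinactivated,1,1.00,1.00,1.96,2.22,4.56,29.88
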