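genotype,catkin_amount,catkin_distribution,sterility_mean,sterility_sd,viability_mean,viability_sd,kmc,hc
Apolda,Very high,Uniform,7.79,0.62,89.05,0.73,1,1
Avellana Speciale,Medium,Apical,39.89,2.34,59.31,2.35,3,2
Barcelona,Low,Apical-uniform,46.07,1.57,53.35,1.63,3,2
Barrettona,Very high,Uniform,41.46,4.37,57.28,4.36,3,2
Camponica,Medium,Apical,46.49,4.16,53.01,4.18,3,2
Carrello,Medium,Uniform,42.2,9.9,56.59,10.34,3,2
Closca Molla,Medium,Apical,55.72,1.16,41.32,1.09,4,2
Comen,Medium,Apical,44.18,2.77,54.72,2.81,3,2
Comune di Sicilia,High,Apical,58.81,3.56,39.62,3.43,4,2
Cosford,Very high,Uniform,13.93,1.43,83.63,1.37,2,1
Daviana,Medium-high,Apical,13.56,0.67,84.19,0.6,2,1
Ennis,High,Apical,3.76,0.43,94.41,0.56,1,1
Fructo Rubro,Medium,Apical,53.31,2.17,42.32,2.16,4,2
Gironell,Medium,Apical,3.37,0.17,94.43,0.21,1,1
Grifoll,Low,Apical,15.05,1.5,82.14,1.53,2,1
Grossal,Medium,Apical,3.52,0.18,94.86,0.31,1,1
Gunslebert,High,Apical,4.35,0.11,94.56,0.13,1,1
Karidaty,Medium,Apical,12.06,0.27,86.10,0.32,2,1
Minnolara,Medium,Uniform,42.11,1.59,57.15,1.56,3,2
Negret,High,Uniform,51.87,2.27,45.2,1.99,4,2
Nocchione,High,Uniform,51.89,4.35,47.04,4.44,4,2
Nocchione Stelliferi A6,High,Apical-uniform,42.48,0.9,55.52,0.83,3,2
Nocchione Stelliferi F6,High,Apical-uniform,44.11,1.98,54.21,2.08,3,2
Nociara,High,Apical,49.99,4.31,49.09,4.4,4,2
Nostrale,High,Uniform,42.3,1.18,56.65,1.24,3,2
Pallagrossa,High,Uniform,6.46,2.45,91.22,2.43,1,1
Piazza Armerina,High,Uniform,57.13,4.46,41.96,4.41,4,2
Racinante,High,Apical,37.08,1.82,62.1,1.89,3,2
Riccia di Talanico,Medium,Apical,48.27,4.22,50.32,4.21,3,2
Santa Maria del Gesu,Medium,Uniform,45.52,1.41,53.96,1.43,3,2
Tombul,Low-medium,Apical,3.88,0.27,94.72,0.34,1,1
Tonda Bianca,Medium,Apical,0.96,0.08,98.13,0.08,1,1
Tonda di Giffoni,High,Uniform,73.58,3.0,23.96,2.8,5,2
Tonda Romana,High,Uniform,45.51,9.3,51.17,9.31,3,2
Vermellet,Medium,Uniform,46.11,5.8,53.27,5.76,3,2
Wild Type 1,Medium-high,Apical,2.64,0.12,97.02,0.16,1,1
Wild Type 2,Medium-high,Apical,1.85,0.3,97.81,0.33,1,1
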