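country,p_low,se_low,cluster_low,p_high,se_high,cluster_high,chi2,chi2_p,printed_diff,printed_se_diff,printed_z
Austria,57.2,2.42,L-3,50.2,0.86,L-1,0.18,0.67,-7,2.4,-2.89
Belgium,49.9,1.94,L-2,41.8,0.62,L-2,0.33,0.57,-8,2,-43
Chile,62.9,2.34,L-3,55.2,0.77,L-1,0.20,0.65,-8,2.5,-39
France,51.3,2.21,L-2,46.5,0.80,L-2,0.08,0.78,-5,2.4,-1.98
Germany,43.1,4.17,L-1,41.1,0.75,L-2,0.00,0.95,-2,4.4,-0.45
Greece,65.5,2.48,H-1,58.5,0.71,H-2,0.14,0.70,-7,2.5,-2.75
Hungary,61.5,3.10,L-3,54.2,0.83,L-1,0.16,0.68,-7,3,-2.41
Israel,52.2,2.53,L-2,43.5,0.73,L-2,0.39,0.53,-9,2.6,-3.39
Korea,59.4,1.90,L-3,54.7,0.79,L-1,0.05,0.81,-5,1.9,-2.43
Mexico,66.1,2.80,H-1,59.4,0.82,H-2,0.13,0.72,-7,2.9,-2.32
Turkey,63.2,2.32,L-3,58.1,0.87,H-2,0.06,0.80,-5,2.5,-25
United States,75.7,2.38,H-2,67.1,0.69,H-2,0.19,0.65,-9,2.4,-3.64
Croatia,55.9,2.77,L-3,46.5,0.86,L-2,0.40,0.52,-9,2.7,-3.46
Russia,40.6,4.40,L-1,51.5,0.80,L-1,0.66,0.41,11,4.2,2.57
United Arab Emirates,58.2,1.21,L-3,62.7,0.70,H-2,0.43,0.83,4,1.3,3.57
OECD average,57.7,0.51,,54.8,0.13,,0.01,0.91,-3,0.5,-5.48
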