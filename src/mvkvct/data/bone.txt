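# Cortical bone (ICRU-44), basis density 1.85 g/cm^3
# NIST-style reference values transcribed for simulation use.
# energy_keV  mu_over_rho_cm2g  muen_over_rho_cm2g
10      28.51     26.80
15      9.032     8.388
20      4.001     3.601
30      1.331     1.070
40      0.6655    0.4507
50      0.4242    0.2336
60      0.3148    0.1400
80      0.2229    0.06896
100     0.1855    0.04585
150     0.1480    0.03183
200     0.1309    0.03003
300     0.1113    0.03032
400     0.09908   0.03069
500     0.09022   0.03073
600     0.08332   0.03052
800     0.07308   0.02973
1000    0.06566   0.02875
1250    0.05871   0.02745
1500    0.05346   0.02629
2000    0.04607   0.02455
3000    0.03745   0.02210
4000    0.03257   0.02047
5000    0.02946   0.01937
6000    0.02729   0.01864
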