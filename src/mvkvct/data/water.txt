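# Liquid water (H2O), density 1.000 g/cm^3
# NIST-style reference values transcribed for simulation use.
# energy_keV  mu_over_rho_cm2g  muen_over_rho_cm2g
10      5.329     4.944
15      1.673     1.374
20      0.8096    0.5503
30      0.3756    0.1557
40      0.2683    0.06947
50      0.2269    0.04223
60      0.2059    0.03190
80      0.1837    0.02597
100     0.1707    0.02546
150     0.1505    0.02764
200     0.1370    0.02967
300     0.1186    0.03192
400     0.1061    0.03279
500     0.09687   0.03299
600     0.08956   0.03284
800     0.07865   0.03206
1000    0.07072   0.03103
1250    0.06323   0.02965
1500    0.05754   0.02833
2000    0.04942   0.02608
3000    0.03969   0.02281
4000    0.03403   0.02066
5000    0.03031   0.01915
6000    0.02770   0.01806
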