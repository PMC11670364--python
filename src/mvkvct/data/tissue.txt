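# Soft tissue (ICRU-44), basis density 1.06 g/cm^3
# NIST-style reference values transcribed for simulation use.
# energy_keV  mu_over_rho_cm2g  muen_over_rho_cm2g
10      5.367     4.964
15      1.693     1.396
20      0.8205    0.5638
30      0.3783    0.1610
40      0.2685    0.07192
50      0.2262    0.04349
60      0.2048    0.03258
80      0.1823    0.02615
100     0.1693    0.02544
150     0.1492    0.02745
200     0.1358    0.02942
300     0.1175    0.03164
400     0.1051    0.03250
500     0.09593   0.03269
600     0.08873   0.03254
800     0.07792   0.03176
1000    0.07006   0.03074
1250    0.06264   0.02938
1500    0.05700   0.02807
2000    0.04896   0.02584
3000    0.03932   0.02261
4000    0.03372   0.02049
5000    0.03004   0.01901
6000    0.02746   0.01795
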