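# Silicon, density 2.33 g/cm^3
# NIST-style reference values transcribed for simulation use.
# energy_keV  mu_over_rho_cm2g  muen_over_rho_cm2g
10      33.89     32.26
15      10.34     9.794
20      4.464     4.076
30      1.436     1.164
40      0.7012    0.4869
50      0.4385    0.2437
60      0.3207    0.1434
80      0.2228    0.06791
100     0.1835    0.04467
150     0.1448    0.03054
200     0.1275    0.02882
300     0.1082    0.02904
400     0.09614   0.02938
500     0.08748   0.02938
600     0.08077   0.02920
800     0.07082   0.02844
1000    0.06361   0.02749
1250    0.05688   0.02632
1500    0.05183   0.02525
2000    0.04480   0.02362
3000    0.03678   0.02133
4000    0.03240   0.01991
5000    0.02967   0.01898
6000    0.02788   0.01842
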