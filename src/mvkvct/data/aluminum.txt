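# Aluminum, density 2.699 g/cm^3 (inherent tube filtration)
# NIST-style reference values transcribed for simulation use.
# energy_keV  mu_over_rho_cm2g  muen_over_rho_cm2g
10      26.23     25.43
15      7.955     7.487
20      3.441     3.094
30      1.128     0.8778
40      0.5685    0.3601
50      0.3681    0.1840
60      0.2778    0.1099
80      0.2018    0.05511
100     0.1704    0.03794
150     0.1378    0.02827
200     0.1223    0.02745
300     0.1042    0.02816
400     0.09276   0.02862
500     0.08445   0.02868
600     0.07802   0.02851
800     0.06841   0.02778
1000    0.06146   0.02686
1250    0.05496   0.02571
1500    0.05006   0.02467
2000    0.04324   0.02311
3000    0.03541   0.02090
4000    0.03106   0.01962
5000    0.02836   0.01882
6000    0.02655   0.01835
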