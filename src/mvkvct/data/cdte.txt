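# Cadmium telluride (CdTe), density 5.85 g/cm^3
# NIST-style reference values transcribed for simulation use; K-edge structure
# (Cd 26.7 keV, Te 31.8 keV) represented by closely spaced grid points.
# energy_keV  mu_over_rho_cm2g  muen_over_rho_cm2g
10      118.0     90.0
15      39.70     33.0
20      18.20     15.5
26.70   8.200     7.00
26.72   15.90     10.0
31.80   10.20     7.40
31.82   15.20     9.50
40      8.580     6.50
50      4.800     3.90
60      3.070     2.50
80      1.440     1.16
100     0.8200    0.640
150     0.3300    0.240
200     0.1920    0.131
300     0.1070    0.0640
400     0.08000   0.0450
500     0.06800   0.0381
600     0.06100   0.0346
800     0.05350   0.0317
1000    0.04900   0.0300
1250    0.04520   0.0288
1500    0.04280   0.0282
2000    0.04000   0.0280
3000    0.03900   0.0289
4000    0.03920   0.0300
5000    0.04000   0.0313
6000    0.04110   0.0326
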