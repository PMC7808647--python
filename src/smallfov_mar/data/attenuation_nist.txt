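# Mass attenuation coefficients mu/rho (cm^2/g) vs photon energy (keV),
# transcribed/log-log-interpolated from the public NIST XCOM database for
# liquid water, cortical bone (ICRU-44), and elemental gold.
# Columns: energy_keV  water  bone  gold
10   5.329    28.51    113.7
20   0.8096   4.001    78.83
30   0.3756   1.331    26.00
40   0.2683   0.6655   11.90
50   0.2269   0.4242   6.630
60   0.2059   0.3148   4.170
70   0.1937   0.2617   2.750
80   0.1837   0.2229   1.940
90   0.1767   0.2023   7.100
100  0.1707   0.1855   5.160
110  0.1657   0.1759   4.300
120  0.1613   0.1676   3.700
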