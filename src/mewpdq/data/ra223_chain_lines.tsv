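# Photon emission lines of Ra-223 in equilibrium with its short-lived
# daughters (Rn-219, Po-215, Pb-211, Bi-211, Tl-207), compiled from
# published evaluated decay data (ICRP Publication 107 / NNDC ENSDF).
# Intensities are photons per Ra-223 decay assuming secular equilibrium
# of the daughters; lines below ~1e-4/decay omitted.
# energy_keV	intensity
74.81	0.0085
77.11	0.0142
81.07	0.1500
83.79	0.2490
87.30	0.0066
94.50	0.0860
97.50	0.0290
122.32	0.0119
130.60	0.0013
144.27	0.0322
154.21	0.0562
158.63	0.0069
269.46	0.1370
271.23	0.1080
323.87	0.0393
338.28	0.0279
342.87	0.0023
351.03	0.1291
371.68	0.0049
401.81	0.0664
404.85	0.0378
427.09	0.0176
438.80	0.0004
445.03	0.0127
704.64	0.0046
766.51	0.0062
831.96	0.0352
897.80	0.0026
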