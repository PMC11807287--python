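# Photon emission lines of Th-227 (X-rays and gammas), compiled from
# published evaluated decay data (ICRP Publication 107 / NNDC ENSDF).
# Intensities are photons per decay; lines below ~1e-4/decay and above
# 400 keV omitted (negligible for the energy windows modeled here).
# energy_keV	intensity
50.13	0.0850
79.72	0.0195
85.43	0.1370
88.47	0.2250
99.60	0.0540
102.30	0.0250
113.17	0.0062
117.20	0.0023
204.08	0.0023
206.08	0.0027
210.62	0.0118
235.96	0.1270
250.40	0.0031
252.50	0.0060
256.23	0.0700
281.42	0.0034
286.09	0.0174
289.59	0.0191
296.50	0.0050
299.98	0.0216
304.50	0.0116
312.70	0.0050
329.85	0.0295
334.37	0.0114
342.60	0.0038
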