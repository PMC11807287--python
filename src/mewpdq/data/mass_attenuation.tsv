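# Mass attenuation coefficients (total with coherent scattering, cm^2/g)
# for liquid water (soft-tissue surrogate) and ICRU-44 cortical bone,
# from the NIST XCOM / Hubbell-Seltzer tabulations.  Interpolated
# log-log between grid points at run time.
# energy_keV	water	cortical_bone
40	0.2683	0.6655
50	0.2269	0.4242
60	0.2059	0.3148
80	0.1837	0.2229
100	0.1707	0.1855
150	0.1505	0.1480
200	0.1370	0.1309
300	0.1186	0.1113
400	0.1061	0.09908
500	0.09687	0.09022
600	0.08956	0.08332
800	0.07865	0.07308
1000	0.07072	0.06566
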