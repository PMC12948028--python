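# Glandular-in-adipose breast tissue optical constants (IMBL configurations)
# mu0: bulk (adipose) linear attenuation; mu: glandular-minus-adipose contrast;
# gamma: delta/beta ratio of the feature.
energy_keV,mu0_per_um,mu_per_um,gamma
26.0,3.35e-5,1.42e-5,642
32.0,2.62e-5,8.50e-6,869
42.0,2.15e-5,4.67e-6,1203
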