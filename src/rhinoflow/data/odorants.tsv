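# Odorant constants at 25 C and 1 atm.
# D_a: diffusivity in air (m^2/s); D_m: diffusivity in mucus (m^2/s);
# beta: air/mucus equilibrium partition coefficient (dimensionless).
name	D_a_m2_s	D_m_m2_s	beta
carvone	6.2e-6	6.9e-10	1.3e-4
amyl_acetate	6.7e-6	7.8e-10	2.5e-3
octane	6.0e-6	7.4e-10	0.48
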