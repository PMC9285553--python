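temperature_C,diffusivity_1e-9_m2_per_s,source
1.0,1.149,"Mills R. (1973) J. Phys. Chem. 77(5):685-688, H2O self-diffusion"
4.0,1.276,"Mills R. (1973) J. Phys. Chem. 77(5):685-688, H2O self-diffusion"
5.0,1.313,"Mills R. (1973) J. Phys. Chem. 77(5):685-688, H2O self-diffusion"
15.0,1.777,"Mills R. (1973) J. Phys. Chem. 77(5):685-688, H2O self-diffusion"
25.0,2.299,"Mills R. (1973) J. Phys. Chem. 77(5):685-688, H2O self-diffusion"
35.0,2.919,"Mills R. (1973) J. Phys. Chem. 77(5):685-688, H2O self-diffusion"
45.0,3.575,"Mills R. (1973) J. Phys. Chem. 77(5):685-688, H2O self-diffusion"
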