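wavelength_nm,eps_hbo,eps_hbr,convention,units,citation
780,1.6934e-4,2.5380e-4,natural_log,mm^-1 uM^-1,"Gratzer/Kollias haemoglobin spectra as compiled by S. Prahl (OMLC), molar base-10 values converted to natural-log per-mm per-uM"
850,2.4361e-4,1.5918e-4,natural_log,mm^-1 uM^-1,"Gratzer/Kollias haemoglobin spectra as compiled by S. Prahl (OMLC), molar base-10 values converted to natural-log per-mm per-uM"
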