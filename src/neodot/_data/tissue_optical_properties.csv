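tissue,wavelength_nm,mua_mm,musp_mm,refractive_index,note
extracerebral,780,0.0164,0.86,1.4,"scalp+skull composite, adult literature range"
extracerebral,850,0.0190,0.80,1.4,"scalp+skull composite, adult literature range"
csf,780,0.0026,0.30,1.4,"effective scattering raised for diffusion validity"
csf,850,0.0041,0.30,1.4,"effective scattering raised for diffusion validity"
grey,780,0.0186,0.84,1.4,"adult cortical grey matter"
grey,850,0.0192,0.76,1.4,"adult cortical grey matter"
white,780,0.0186,1.08,1.4,"adult white matter"
white,850,0.0208,0.94,1.4,"adult white matter"
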