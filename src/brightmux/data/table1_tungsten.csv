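label,center_nm,fwhm_nm,dabsyl,Rhod110,TAMRA,SRhod101,HTX,Cy5
438,438,29.5,1.000,0.220,0.078,0.177,0.374,0.050
510,510,15,0.606,1.000,0.553,0.373,0.483,0.089
549,549,17.6,0.203,0.494,1.000,0.688,0.663,0.274
580,580,21.2,0.114,0.210,0.487,1.000,0.849,0.523
620,620,19.3,0.077,0.129,0.057,0.170,1.000,0.878
676,676,39.9,0.063,0.102,0.034,0.061,0.471,1.000
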