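label,center_nm,fwhm_nm,dabsyl,Rhod110,TAMRA,SRhod101,HTX,Cy5
390,390,22.4,0.547,0.062,0.085,0.116,0.123,0.027
415,415,15.3,0.816,0.053,0.098,0.101,0.211,0.013
438,438,29.5,0.952,0.078,0.042,0.098,0.266,0.013
475,475,33.7,1.000,0.411,0.093,0.076,0.268,0.019
504,504,17,0.580,0.958,0.370,0.150,0.450,0.017
513,513,22.4,0.444,1.000,0.481,0.213,0.439,0.024
549,549,20.8,0.080,0.156,1.000,0.565,0.749,0.060
580,580,21.2,-0.018,0.042,0.506,0.985,0.804,0.174
605,605,22,0.002,0.025,0.029,1.000,1.000,0.373
620,620,19.3,0.017,0.046,0.018,0.167,0.918,0.420
660,660,20.2,0.005,0.024,0.005,0.006,0.520,1.000
689,689,29.5,0.000,0.029,0.007,0.001,0.136,0.132
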