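# Judd-Vos modified photopic luminous efficiency V_M(lambda)
# 10 nm tabulation (peak pinned to 1.0 at 555 nm); interpolated to 1 nm on load.
# wavelength_nm,efficiency
380,0.0002
390,0.0008
400,0.0028
410,0.0074
420,0.0175
430,0.0273
440,0.0379
450,0.0468
460,0.0600
470,0.0910
480,0.1390
490,0.2080
500,0.3230
510,0.5030
520,0.7100
530,0.8620
540,0.9540
550,0.9950
555,1.0000
560,0.9950
570,0.9520
580,0.8700
590,0.7570
600,0.6310
610,0.5030
620,0.3810
630,0.2650
640,0.1750
650,0.1070
660,0.0610
670,0.0320
680,0.0170
690,0.0082
700,0.0041
710,0.0021
720,0.00105
730,0.00052
740,0.00025
750,0.00012
760,0.00006
770,0.00003
780,0.000015
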