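project_label	n_patients
BRCA	1034
UCEC	546
KIRC	525
HNSC	520
LUAD	488
THCA	487
LGG	469
LUSC	468
PRAD	446
COAD	418
GBM	399
BLCA	379
OV	371
STAD	361
LIHC	341
CESC	289
KIRP	280
SARC	249
PAAD	176
PCPG	174
READ	162
ESCA	146
THYM	114
KICH	112
SKCM	102
ACC	90
TGCT	87
MESO	79
UVM	65
UCS	56
DLBC	47
CHOL	43
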