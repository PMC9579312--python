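# Fractional tissue composition (volume fractions) used by the composition-based
# tissue:plasma partition-coefficient method of Poulin & Theil (2002,
# J Pharm Sci 91:129-156), human values: water (f_water), neutral lipids
# (f_nlip) and phospholipids (f_plip) per mL of tissue or plasma.
# "stomach" reuses the intestinal values; "rest" is a muscle/skin average.
tissue	f_water	f_nlip	f_plip
plasma	0.945	0.0035	0.00225
brain	0.770	0.0510	0.05650
gut	0.718	0.0487	0.01630
stomach	0.718	0.0487	0.01630
heart	0.758	0.0115	0.01660
kidney	0.783	0.0207	0.01620
liver	0.751	0.0348	0.02520
lung	0.811	0.0030	0.00900
muscle	0.760	0.0238	0.00720
spleen	0.788	0.0201	0.01980
rest	0.740	0.0260	0.00900
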