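accession	name	log2fc	fdr
P08107	Heat shock 70 kDa protein 1A/1B	-0.62	0.000075
P14618	Pyruvate kinase PKM	-1.12	0.000187
P00558	Phosphoglycerate kinase 1	-2.28	0.000396
P0C0L5	Complement C4-B	2.48	0.001869
P07237	Protein disulfide-isomerase	-0.68	0.002520
P02671	Fibrinogen alpha chain	1.73	0.003736
P02748	Complement component C9	1.39	0.003736
P05156	Complement factor I	0.47	0.003736
P04406	Glyceraldehyde-3-phosphate dehydrogenase	-1.50	0.003736
P02675	Fibrinogen beta chain	1.48	0.003894
P02751	Fibronectin	1.63	0.005073
P01031	Complement C5	0.59	0.007604
P02679	Fibrinogen gamma chain	1.60	0.007648
P05155	Plasma protease C1 inhibitor	1.49	0.007648
P01024	Complement C3	1.08	0.008591
P08603	Complement factor H	0.97	0.010488
P10599	Thioredoxin	-1.02	0.012139
P05164	Myeloperoxidase	1.23	0.012872
P34932	Heat shock 70 kDa protein 4	-0.73	0.019327
P02768	Serum albumin	1.05	0.019750
P62805	Histone H4	1.38	0.020198
P18669	Phosphoglycerate mutase 1	-1.07	0.021136
P04075	Fructose-bisphosphate aldolase A	-0.89	0.021136
P02652	Apolipoprotein A-II	3.34	0.023220
P60709	Actin, cytoplasmic 1	-0.60	0.023220
Q96HE7	ERO1-like protein alpha	-0.90	0.025640
P06733	Alpha-enolase	-1.04	0.029925
P12956	X-ray repair cross-complementing protein 6	0.40	0.030974
P11142	Heat shock cognate 71 kDa protein	-0.56	0.032450
P00338	L-lactate dehydrogenase A chain	-0.83	0.032450
Q99829	Copine-1	0.85	0.032993
P17931	Galectin-3	-1.32	0.036387
P61158	Actin-related protein 3	-1.28	0.036525
Q99623	Prohibitin-2	0.66	0.040969
P99999	Cytochrome c	1.19	0.040969
O75083	WD repeat-containing protein 1	-1.08	0.040969
P12724	Eosinophil cationic protein	1.69	0.042247
P19827	Inter-alpha-trypsin inhibitor heavy chain H1	0.69	0.043209
P00738	Haptoglobin	1.18	0.044182
P62318	Small nuclear ribonucleoprotein Sm D3	1.09	0.045532
P61457	Pterin-4-alpha-carbinolamine dehydratase	0.87	0.050922
P02654	Apolipoprotein C-I	2.52	0.051262
P00736	Complement C1r subcomponent	0.33	0.051262
P08311	Cathepsin G	1.38	0.053989
O14732	Inositol monophosphatase 2	-0.43	0.101858
P0C0L4	Complement C4-A	1.60	0.115126
P36222	Chitinase-3-like protein 1	1.09	0.125089
P27105	Erythrocyte band 7 integral membrane protein	1.50	0.150589
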