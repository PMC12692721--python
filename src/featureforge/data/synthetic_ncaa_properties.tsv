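# SYNTHETIC ncAA property extension (AAindexNC-style layout: three-letter
# code, accession, value). Values are synthetic test data, not measurements.
code	accession	value
MSE	KARS160108	0.428
HYP	KARS160108	-0.571
MLY	KARS160108	2.654
MLZ	KARS160108	-1.609
PCA	KARS160108	0.662
CSO	KARS160108	-0.143
OCS	KARS160108	-0.355
SEP	KARS160108	1.066
TPO	KARS160108	-1.818
PTR	KARS160108	-0.985
MSE	MUNV940102	-0.114
HYP	MUNV940102	1.741
MLY	MUNV940102	0.089
MLZ	MUNV940102	0.896
PCA	MUNV940102	-1.863
CSO	MUNV940102	-1.239
OCS	MUNV940102	0.97
SEP	MUNV940102	-0.628
TPO	MUNV940102	-0.063
PTR	MUNV940102	0.731
MSE	MUNV940103	-2.205
HYP	MUNV940103	-1.201
MLY	MUNV940103	-0.094
MLZ	MUNV940103	-1.546
PCA	MUNV940103	-0.711
CSO	MUNV940103	-0.042
OCS	MUNV940103	-0.665
SEP	MUNV940103	-0.269
TPO	MUNV940103	0.041
PTR	MUNV940103	1.33
MSE	MIYS990102	1.579
HYP	MIYS990102	-0.395
MLY	MIYS990102	-0.828
MLZ	MIYS990102	0.889
PCA	MIYS990102	0.511
CSO	MIYS990102	0.249
OCS	MIYS990102	-0.908
SEP	MIYS990102	0.645
TPO	MIYS990102	0.872
PTR	MIYS990102	-1.785
MSE	PTIO830101	1.017
HYP	PTIO830101	-0.073
MLY	PTIO830101	-0.743
MLZ	PTIO830101	-1.577
PCA	PTIO830101	-0.342
CSO	PTIO830101	-0.061
OCS	PTIO830101	-0.375
SEP	PTIO830101	-1.204
TPO	PTIO830101	-1.195
PTR	PTIO830101	0.705
MSE	PONP800104	0.048
HYP	PONP800104	0.285
MLY	PONP800104	0.629
MLZ	PONP800104	0.718
PCA	PONP800104	1.735
CSO	PONP800104	-0.071
OCS	PONP800104	-0.259
SEP	PONP800104	-0.958
TPO	PONP800104	0.249
PTR	PONP800104	0.264
MSE	KYTJ820101	-0.76
HYP	KYTJ820101	-0.033
MLY	KYTJ820101	-0.018
MLZ	KYTJ820101	3.664
PCA	KYTJ820101	-0.511
CSO	KYTJ820101	1.246
OCS	KYTJ820101	0.407
SEP	KYTJ820101	-0.092
TPO	KYTJ820101	0.408
PTR	KYTJ820101	0.358
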