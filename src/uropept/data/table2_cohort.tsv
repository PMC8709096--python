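condition	n_subjects
Acute kidney injury	422
ADPKD	273
Amyloidosis	8
Atypical hemolytic uremic syndrome	8
C3 glomerulopathy	24
CAKUT	567
Diabetes Mellitus	4428
Diabetic kidney disease	1401
Fanconi syndrom	12
FSGS	126
IgAN	811
MCD	50
MGN	113
Morbus Fabry	66
MPGN	50
Hypertensive nephrosclerosis	104
Nephrotic syndrom	127
Kidney transplantation	2300
SLE	20
LN	94
Vasculitis	159
Healthy control	4864
Total	16027
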