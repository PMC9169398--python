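# Fitted coefficients of the centered linear rate-of-development function
# for time-to-flowering in the Jamapa x Calima RI family (full precision),
# plus the across-site environmental means used for centering.
# Columns: term, factor, locus, value
term	factor	locus	value
center	.	.	0.0235198065831426
alpha	DL	.	-0.0015423214758081
alpha	Srad	.	-0.0000853054955707
alpha	Tmax	.	0.0005966415621148
alpha	Tmin	.	0.0005228804696115
beta	.	TF1	0.0009382848209270
beta	.	TF2	0.0012733168457595
beta	.	TF3	-0.0006810089804720
beta	.	TF4	0.0002546737990060
beta	.	TF5	-0.0000294375056886
beta	.	TF6	0.0005598758808943
beta	.	TF7	-0.0004332155371734
beta	.	TF8	-0.0002159196193359
beta	.	TF9	-0.0004693200551048
beta	.	TF10	-0.0002745608987544
beta	.	TF11	0.0003463304080702
beta	.	TF12	-0.0001723147103969
theta	.	TF1:TF2	0.0002794695951983
gamma	DL	TF3	-0.0007636661891134
gamma	DL	TF7	-0.0001527383245705
gamma	DL	TF12	-0.0001400623472723
gamma	Tmin	TF2	-0.0000298150506285
gamma	Tmin	TF3	-0.0000818315988969
gamma	Tmax	TF5	0.0000980123505664
gamma	Srad	TF12	-0.0000274938204046
centering	DL	.	12.37
centering	Srad	.	18.218
centering	Tmax	.	27.458
centering	Tmin	.	16.128
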