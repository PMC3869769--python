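probe_id	gene_symbol	location	weight	new_weight
204204_at	SLC31A2	9q31-q32	-0.025	-0.507
219748_at	TREML2	6p21.1	-0.033	-0.38
203708_at	PDE4B	1p31	-0.053	-0.319
201990_s_at	CREBL2	12p13	-0.046	-0.314
219049_at	CSGALNACT1	8p21.3	-0.037	-0.226
218751_s_at	FBXW7	4q31.3	-0.044	-0.184
212055_at	C18orf10	18q12.2	0.025	-0.184
205990_s_at	WNT5A	3p21-p14	-0.065	-0.077
204786_s_at	IFNAR2	21q22.1, 21q22.11	-0.033	-0.0522
217825_s_at	UBE2J1	6q15	-0.02	0.0401
201889_at	FAM3C	7q31	-0.039	0.074
206405_x_at	USP6	17p13	-0.038	0.0888
203895_at	PLCB4	20p12	-0.015	0.0982
212122_at	RHOQ	2p21	-0.016	0.137
205862_at	GREB1	2p25.1	-0.034	0.187
221210_s_at	NPL	1q25	0.032	0.189
213555_at	RWDD2A	6q14.2	-0.019	0.195
217104_at	ST20	15q25.1	0.012	0.201
202043_s_at	SMS	Xp22.1	0.011	0.486
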