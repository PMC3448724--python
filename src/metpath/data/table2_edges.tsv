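# Interaction partners of the worked-example compound C07277 and enzyme YLL058W.
# Columns: node_a	node_b	score	kind
C07277	C00103	409	cc
C07277	C00363	441	cc
C07277	C00507	416	cc
C07277	C03319	446	cc
C07277	C11912	63	cc
C07277	YDL055C	298	cp
YLL058W	C00087	317	cp
YLL058W	C00109	900	cp
YLL058W	C00155	900	cp
YLL058W	C00283	317	cp
YLL058W	C00542	904	cp
YLL058W	C01077	900	cp
YLL058W	C02291	900	cp
YLL058W	C05688	900	cp
YLL058W	C05699	900	cp
YLL058W	YAL012W	463	pp
YLL058W	YGL184C	241	pp
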