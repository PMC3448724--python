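# Pathway-class tags for the C07277 / YLL058W worked example.
# Columns: node_id	kind	classes
C07277	compound	M9
YLL058W	enzyme	M2,M5
C00103	compound	M1,M9,M10
C00363	compound	M4
C00507	compound	M1
C03319	compound	M9,M10
C11912	compound	M9
YDL055C	enzyme	M1
C00087	compound	M2
C00109	compound	M1,M5
C00155	compound	M2,M5
C00283	compound	M2,M5
C00542	compound	M2
C01077	compound	M2,M5
C02291	compound	M5
C05688	compound	M6
C05699	compound	M6
YAL012W	enzyme	M2,M5
YGL184C	enzyme	M2,M5
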