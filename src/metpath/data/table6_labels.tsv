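# Pathway-class tags for the C00439 worked example.
# Columns: node_id	kind	classes
C00439	compound	M5
C01045	compound	M5
C00785	compound	M5
C00101	compound	M5,M8
C00025	compound	M5,M8
C00014	compound	M5
C03680	compound	M5
C01817	compound	M5
C05568	compound	M5
C00135	compound	M5
C00073	compound	M5
C02170	compound	M5
C00445	compound	M8
C00001	compound	M8
C00018	compound	M8
C00664	compound	M8
C03479	compound	M8
C14818	compound	M8
C14819	compound	M8
C00504	compound	M8
C00234	compound	M8
C00992	compound	M8
C00440	compound	M8
YGL125W	enzyme	M8
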