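# Interaction partners of the misclassified compound C00439 (true class M5,
# 1-st order prediction M8). 23 distinct partners; C00101 and C00025 belong to
# both M5 and M8 (see table6_labels.tsv).
# Columns: node_a	node_b	score	kind
C00439	C01045	940	cc
C00439	C00785	938	cc
C00439	C00101	934	cc
C00439	C00025	923	cc
C00439	C00014	901	cc
C00439	C03680	899	cc
C00439	C01817	511	cc
C00439	C05568	388	cc
C00439	C00135	302	cc
C00439	C00073	283	cc
C00439	C02170	191	cc
C00439	C00445	927	cc
C00439	C00001	899	cc
C00439	C00018	899	cc
C00439	C00664	899	cc
C00439	C03479	899	cc
C00439	C14818	899	cc
C00439	C14819	899	cc
C00439	C00504	739	cc
C00439	C00234	438	cc
C00439	C00992	378	cc
C00439	C00440	205	cc
C00439	YGL125W	177	cp
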