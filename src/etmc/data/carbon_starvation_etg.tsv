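# Reconstruction of the E. coli carbon-starvation event transition graph.
# SYNTHETIC: the published graph is available only as a figure; this edge
# list is a best-effort reconstruction satisfying the printed structural
# facts (11 nodes, 22 edges, 2 edges absent under carbon starvation) and
# the textual interaction claims: Fis represses crp (fis:+ -> crp:-),
# DNA-supercoiling couplings among fis, gyrAB and topA, and the carbon
# starvation signal feeding the cAMP-CRP complexation partners crp and
# cya. crp and cya are exact structural twins (the graph automorphism
# swapping them fixes everything else), which makes their predicted
# growth behavior identical. Replace this file with the true edge list
# if it becomes available.
# auxiliaries: signal
# conditions: starvation no-starvation
source	target	condition
gyrAB:+	fis:+
fis:+	gyrAB:-
gyrAB:-	fis:-
fis:-	gyrAB:+
fis:+	topA:+
topA:+	fis:-
fis:-	topA:-
topA:-	gyrAB:+
topA:+	gyrAB:-
fis:+	crp:-
fis:+	cya:-
crp:-	fis:+
cya:-	fis:+
fis:-	crp:+
fis:-	cya:+
crp:+	fis:-
cya:+	fis:-
crp:+	signal:+
cya:+	signal:+
signal:+	fis:+
signal:+	crp:+	no-starvation
signal:+	cya:+	no-starvation
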