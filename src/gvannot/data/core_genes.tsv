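# Curated reference list of the 37 baculovirus core genes used for the
# presence/absence audit (name<TAB>aliases, comma separated).
# Assembled from the standard core-gene inventory of the family.
p74	pif-0
pif-1
pif-2
pif-3
pif-4	odv-28
pif-5	odv-e56
pif-6
pif-7	ac110
vp91	pif-8,p95
lef-1
lef-2
dnapol	dna-polymerase
helicase	p143
alk-exo	an
lef-4
lef-5
lef-8
lef-9
p47
vlf-1
p6.9
vp39
vp1054
gp41
odv-e18
odv-e25
odv-ec27
odv-ec43	ac109
p33	ac92
p18	ac93
p40	ac101
p48	ac103
p49	ac142
38k	ac98
desmoplakin	ac66
ac53
ac78
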