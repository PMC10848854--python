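# Gene-name normalisation map (lower-cased input -> canonical label).
# Edit or extend to cope with the naming habits of other annotation sources.
# tRNA and rRNA names are additionally handled by pattern rules in
# mitochar.io (tRNA-Met / trnM / tRNA-Met2 all normalise to trnM / trnM2).
cox1: Cox1
coxi: Cox1
co1: Cox1
coi: Cox1
cox2: Cox2
coxii: Cox2
co2: Cox2
coii: Cox2
cox3: Cox3
coxiii: Cox3
co3: Cox3
coiii: Cox3
cob: Cytb
cytb: Cytb
cyb: Cytb
nad1: Nad1
nd1: Nad1
nad2: Nad2
nd2: Nad2
nad3: Nad3
nd3: Nad3
nad4: Nad4
nd4: Nad4
nad4l: Nad4L
nd4l: Nad4L
nad5: Nad5
nd5: Nad5
nad6: Nad6
nd6: Nad6
atp6: Atp6
atpase6: Atp6
atp8: Atp8
atpase8: Atp8
rrnl: rrnL
16s: rrnL
lrrna: rrnL
lsu: rrnL
rrns: rrnS
12s: rrnS
srrna: rrnS
ssu: rrnS
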