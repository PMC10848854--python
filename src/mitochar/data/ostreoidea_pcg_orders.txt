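# Linearised protein-coding gene orders of the two gryphaeid oysters,
# read from the Cox1 origin.  Atp8 is excluded throughout: it is absent
# from the Hyotissa sinensis mitogenome, so the comparable PCG set is the
# 12 genes listed here.  On that gene set the two orders are identical.
> Hyotissa_sinensis
Cox1 Nad1 Nad3 Cox2 Cytb Nad2 Nad5 Nad6 Nad4 Atp6 Nad4L Cox3
> Hyotissa_hyotis
Cox1 Nad1 Nad3 Cox2 Cytb Nad2 Nad5 Nad6 Nad4 Atp6 Nad4L Cox3
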