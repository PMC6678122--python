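library	phase	raw_reads	clean_reads	unique_tags	conserved_mirnas	novel_mirnas
MpSI-1	I	31711290	21400622	2757270	174	87
MpSI-2	I	31959711	21401693	2876894	172	82
MpSI-3	I	31763941	21217533	2882107	168	68
MpSII-1	II	27733326	17612476	3066337	157	70
MpSII-2	II	33988872	21414373	3427062	165	64
MpSII-3	II	31143787	19377920	2942567	183	83
MpSIII-1	III	31167480	20039686	2593393	163	97
MpSIII-2	III	32681945	20872904	2774500	162	93
MpSIII-3	III	31100220	19792612	2443701	160	94
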