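library	phase	conserved_mirna_reads
MpSI-1	I	1723573
MpSI-2	I	1519586
MpSI-3	I	1115971
MpSII-1	II	777660
MpSII-2	II	823736
MpSII-3	II	1207854
MpSIII-1	III	1230083
MpSIII-2	III	1206643
MpSIII-3	III	1271965
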