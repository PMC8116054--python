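taxon,state
Pan,high
A_afarensis,low
A_africanus,high
A_sediba,high
A_garhi,high
P_robustus,high
P_boisei,high
H_habilis,high
H_floresiensis,high
H_erectus,low
H_naledi,low
H_sapiens,low
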