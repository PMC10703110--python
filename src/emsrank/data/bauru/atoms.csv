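atom_id,name
1,Geisel
2,Nacoes
3,Ipiranga
4,Mary Dota
5,Bela Vista
6,Boulevard
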