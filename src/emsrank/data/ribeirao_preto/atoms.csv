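atom_id,name
1,Central
2,North
3,South
4,East
5,West
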