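atom_id,priority,rate_per_hour
1,serious,0.0669
1,regular,0.9140
2,serious,0.0469
2,regular,1.1014
3,serious,0.0937
3,regular,0.7968
4,serious,0.0234
4,regular,0.3281
5,serious,0.0469
5,regular,0.7265
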