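atom_id,priority,rate_per_hour
1,serious,0.0871
1,regular,0.4876
2,serious,0.0522
2,regular,0.7140
3,serious,0.0697
3,regular,0.3483
4,serious,0.0348
4,regular,0.4179
5,serious,0.1045
5,regular,0.8359
6,serious,0.0174
6,regular,0.1741
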