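from_atom,to_atom,minutes
1,1,8.7
1,2,9.5
1,3,10.9
1,4,11.4
1,5,9.9
2,1,9.5
2,2,11.6
2,3,9.7
2,4,7.3
2,5,7.5
3,1,10.9
3,2,9.7
3,3,8.6
3,4,13.5
3,5,10.7
4,1,11.4
4,2,7.3
4,3,13.5
4,4,10.1
4,5,15.1
5,1,9.9
5,2,7.5
5,3,10.7
5,4,15.1
5,5,9.2
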