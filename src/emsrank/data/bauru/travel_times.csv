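from_atom,to_atom,minutes
1,1,8.2
1,2,13.7
1,3,13.2
1,4,9.9
1,5,10.0
1,6,7.6
2,1,13.7
2,2,11.7
2,3,15.0
2,4,16.0
2,5,15.0
2,6,9.0
3,1,13.2
3,2,15.0
3,3,8.7
3,4,15.3
3,5,17.0
3,6,11.0
4,1,9.9
4,2,16.0
4,3,15.3
4,4,10.8
4,5,15.0
4,6,7.4
5,1,10.0
5,2,15.0
5,3,17.0
5,4,15.0
5,5,8.8
5,6,11.0
6,1,7.6
6,2,9.0
6,3,11.0
6,4,7.4
6,5,11.0
6,6,7.6
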