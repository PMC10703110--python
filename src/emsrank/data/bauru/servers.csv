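server_type,count,dedicated,base_atom,mean_service_time_min
BSU,7,0,,43.9
ASU,2,1,1,55.5
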