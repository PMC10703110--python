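server_type,count,dedicated,base_atom,mean_service_time_min
BSU,9,0,,37.3
ASU,1,1,1,47.2
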