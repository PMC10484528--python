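source_id,time_ms
2,53.0
3,88.0
4,100.0
4,212.0
2,258.0
2,300.0
1,355.0
2,424.0
0,446.0
2,457.0
3,466.0
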