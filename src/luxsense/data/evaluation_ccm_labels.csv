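child_id,label
001,Hypo-sensitive
002,normal
003,Hyper-sensitive
004,Normal
005,Hypo-sensitive
006,Hyper-sensitive
007,Hypo-sensitive
008,Normal
009,Hyper-sensitive
010,Hypo-sensitive
011,Hypo-sensitive
012,Normal
013,Hypo-sensitive
014,Normal
015,Hyper-sensitive
016,Normal
017,Hypo-sensitive
018,Hyper-sensitive
019,Hypo-sensitive
020,Normal
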