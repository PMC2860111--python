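label	total	leading	lagging
CAI < 0.35	1958	1087	871
0.35 < CAI < 0.65	721	434	287
CAI > 0.65	61	41	20
Ribosomal	52	44	8
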