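pairing_type	s
WC	0.0
G:U	0.41
I:C	0.28
I:A	0.9999
U:G	0.68
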