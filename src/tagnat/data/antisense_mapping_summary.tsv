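sample_id	unambiguous_total	unambiguous_distinct	genes_detected
5Y127	247816	15192	6472
5Y212	262353	14966	6398
5Y339	249595	15483	6585
65505	247940	13957	6227
65530	266926	15289	6346
65540	265599	16346	6758
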