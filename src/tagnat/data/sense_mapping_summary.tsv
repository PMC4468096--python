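sample_id	unambiguous_total	unambiguous_distinct	genes_detected
5Y127	2412224	43158	10391
5Y212	2529818	43175	10209
5Y339	2519260	45369	10666
65505	2583990	40595	10434
65530	2668978	43910	10137
65540	2489004	47775	10298
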