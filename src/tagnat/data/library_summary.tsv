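sample_id	group	raw_total	raw_distinct	clean_total	clean_distinct
5Y127	F	5259561	355014	4917435	119886
5Y212	F	5364832	350472	5033144	117880
5Y339	F	5145452	336695	4857460	120525
65505	S	5244848	314710	4930422	110879
65530	S	5485701	343795	5184375	117642
65540	S	5282704	373209	4941669	143800
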