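gene	drug_class	chrom	start	end
ADRB1	beta_blocker	10	115803625	115806663
CACNA1C	calcium_channel_blocker	3	53528638	53847760
CACNA1D	calcium_channel_blocker	X	49061523	49089802
CACNA1F	calcium_channel_blocker	7	81575760	82073272
CACNA1S	calcium_channel_blocker	3	50400044	50541675
CACNA2D1	calcium_channel_blocker	1	201008640	201081554
CACNA2D2	calcium_channel_blocker	17	37329706	37353922
CACNB1	calcium_channel_blocker	10	18429353	18832486
CACNB2	calcium_channel_blocker	12	49208263	49222724
CACNB3	calcium_channel_blocker	2	152689285	152955681
CACNB4	calcium_channel_blocker	17	65040670	65052913
CACNG1	calcium_channel_blocker	12	2162153	2807116
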