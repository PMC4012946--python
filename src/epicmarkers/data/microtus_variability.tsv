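marker_id	het_Mlus	het_Mduo	alignment_length	n_differences	indels
Abcb9-2	0	0	403	1
Agxt-10	0	0	376	2	1;1
Catsper3-5	0	0	311	6	4;10
Dhcr24-7	1	1	340	3
Ivd-8	1	1	528	3	3
Nadsyn1-4	3	0	491	4
Rras-4	1	0	506	1	6
Smo-9	0	0	398	4
Wls-7	3	0	367	4
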