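marker	ensembl_gene	intron_length_ref	forward	reverse
Abcb9-2	ENSMUSG00000029408	423	GCATYGTSATCCAGAARAGCAYGGA	CTGTGCGRTTCTCRTCRAARAAGCT
Agxt-10	ENSMUSG00000026272	420	GGCTACAACTGGAGGGACATC	TGCAGGGCCTCCYTCAGGGCCT
Catsper3-5	ENSMUSG00000021499	382	TGCTKGCMTCSTTCATCTT	AGRATYAYYTGCTTCTYCTCC
Dhcr24-7	ENSMUSG00000034926	357	CAGGACATGCTGGTGCCCATGAA	CCTGGCTGGCTGGGCAGGATGAA
Ivd-8	ENSMUSG00000027332	478	CTGGACCTRGARCGCCTGGT	CTGRAAKTGSCCRATYTTCT
Nadsyn1-4	ENSMUSG00000031090	498	GTYCGYTACAAYTGCAGAGT	TCCTKSHCCAKGGGGTRAACCA
Rras-4	ENSMUSG00000038387	488	ACWCAGATCCTCMGRGTYAAGGA	AGTTTGGCDGAKGCCTCRAAGTA
Smo-9	ENSMUSG00000001761	344	GCCACCCTGCTCATCTGGAGGCG	TTGGCRATCATCTTGCTYTTCTTGA
Trpv4-8	ENSMUSG00000014158	398	TTACCRBACCACVGYGGACTACCT	CTGGAAGGAGCCRTCGAYGAAGA
Wls-7	ENSMUSG00000028173	364	AAYCACATYGCMGGSTAYTGGAA	TCYGTKCCAACRTCYGTRGTCCA
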