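name	direction	adapter	barcode	spacer	priming	full_oligo
f1	forward	ACACTCTTTCCCTACACGACGCTCTTCCGATCT	TGTGTCTCAACA		GTGYCAGCMGCCGCGGTAA	ACACTCTTTCCCTACACGACGCTCTTCCGATCTTGTGTCTCAACAGTGYCAGCMGCCGCGGTAA
f2	forward	ACACTCTTTCCCTACACGACGCTCTTCCGATCT	GATCGAGTTGTT	A	GTGYCAGCMGCCGCGGTAA	ACACTCTTTCCCTACACGACGCTCTTCCGATCTGATCGAGTTGTTAGTGYCAGCMGCCGCGGTAA
f3	forward	ACACTCTTTCCCTACACGACGCTCTTCCGATCT	CAACAGTGAGGG	TC	GTGYCAGCMGCCGCGGTAA	ACACTCTTTCCCTACACGACGCTCTTCCGATCTCAACAGTGAGGGTCGTGYCAGCMGCCGCGGTAA
f4	forward	ACACTCTTTCCCTACACGACGCTCTTCCGATCT	GACATTACCACC	TTC	GTGYCAGCMGCCGCGGTAA	ACACTCTTTCCCTACACGACGCTCTTCCGATCTGACATTACCACCTTCGTGYCAGCMGCCGCGGTAA
f5	forward	ACACTCTTTCCCTACACGACGCTCTTCCGATCT	CGTAGAGCATTT	CTAT	GTGYCAGCMGCCGCGGTAA	ACACTCTTTCCCTACACGACGCTCTTCCGATCTCGTAGAGCATTTCTATGTGYCAGCMGCCGCGGTAA
f6	forward	ACACTCTTTCCCTACACGACGCTCTTCCGATCT	TTACAGCCCGTA	GCCAA	GTGYCAGCMGCCGCGGTAA	ACACTCTTTCCCTACACGACGCTCTTCCGATCTTTACAGCCCGTAGCCAAGTGYCAGCMGCCGCGGTAA
f7	forward	ACACTCTTTCCCTACACGACGCTCTTCCGATCT	CTCTGCACGGTA	GCCAGG	GTGYCAGCMGCCGCGGTAA	ACACTCTTTCCCTACACGACGCTCTTCCGATCTCTCTGCACGGTAGCCAGGGTGYCAGCMGCCGCGGTAA
f8	forward	ACACTCTTTCCCTACACGACGCTCTTCCGATCT	GGACACCGAAGA	GTGAGGT	GTGYCAGCMGCCGCGGTAA	ACACTCTTTCCCTACACGACGCTCTTCCGATCTGGACACCGAAGAGTGAGGTGTGYCAGCMGCCGCGGTAA
f9	forward	ACACTCTTTCCCTACACGACGCTCTTCCGATCT	CAGTCTTAATTG		GTGYCAGCMGCCGCGGTAA	ACACTCTTTCCCTACACGACGCTCTTCCGATCTCAGTCTTAATTGGTGYCAGCMGCCGCGGTAA
f10	forward	ACACTCTTTCCCTACACGACGCTCTTCCGATCT	GGTGCATACTTT	C	GTGYCAGCMGCCGCGGTAA	ACACTCTTTCCCTACACGACGCTCTTCCGATCTGGTGCATACTTTCGTGYCAGCMGCCGCGGTAA
f11	forward	ACACTCTTTCCCTACACGACGCTCTTCCGATCT	TCAGCTTAAATC	CA	GTGYCAGCMGCCGCGGTAA	ACACTCTTTCCCTACACGACGCTCTTCCGATCTTCAGCTTAAATCCAGTGYCAGCMGCCGCGGTAA
f12	forward	ACACTCTTTCCCTACACGACGCTCTTCCGATCT	CTGATGGGGGCG	TAG	GTGYCAGCMGCCGCGGTAA	ACACTCTTTCCCTACACGACGCTCTTCCGATCTCTGATGGGGGCGTAGGTGYCAGCMGCCGCGGTAA
r1	reverse	GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT	TGTGTCTCAACA	TACTAGT	GGACTACNVGGGTWTCTAAT	GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCTTGTGTCTCAACATACTAGTGGACTACNVGGGTWTCTAAT
r2	reverse	GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT	GATCGAGTTGTT	GATCGC	GGACTACNVGGGTWTCTAAT	GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCTGATCGAGTTGTTGATCGCGGACTACNVGGGTWTCTAAT
r3	reverse	GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT	CAACAGTGAGGG	CAAAT	GGACTACNVGGGTWTCTAAT	GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCTCAACAGTGAGGGCAAATGGACTACNVGGGTWTCTAAT
r4	reverse	GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT	GACATTACCACC	ATCC	GGACTACNVGGGTWTCTAAT	GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCTGACATTACCACCATCCGGACTACNVGGGTWTCTAAT
r5	reverse	GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT	CGTAGAGCATTT	TAC	GGACTACNVGGGTWTCTAAT	GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCTCGTAGAGCATTTTACGGACTACNVGGGTWTCTAAT
r6	reverse	GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT	TTACAGCCCGTA	TA	GGACTACNVGGGTWTCTAAT	GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCTTTACAGCCCGTATAGGACTACNVGGGTWTCTAAT
r7	reverse	GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT	CTCTGCACGGTA	C	GGACTACNVGGGTWTCTAAT	GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCTCTCTGCACGGTACGGACTACNVGGGTWTCTAAT
r8	reverse	GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT	GGACACCGAAGA		GGACTACNVGGGTWTCTAAT	GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCTGGACACCGAAGAGGACTACNVGGGTWTCTAAT
pcr2_f	pcr2_forward	AATGATACGGCGACCACCGAGATCTACAC			ACACTCTTTCCCTACACGACGCTCTTCCGATCT	AATGATACGGCGACCACCGAGATCTACACACACTCTTTCCCTACACGACGCTCTTCCGATCT
i1	pcr2_reverse	CAAGCAGAAGACGGCATACGAGAT	ATCACG		AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC	CAAGCAGAAGACGGCATACGAGATATCACGAGATCGGAAGAGCACACGTCTGAACTCCAGTCAC
i2	pcr2_reverse	CAAGCAGAAGACGGCATACGAGAT	CGATGT		AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC	CAAGCAGAAGACGGCATACGAGATCGATGTAGATCGGAAGAGCACACGTCTGAACTCCAGTCAC
i3	pcr2_reverse	CAAGCAGAAGACGGCATACGAGAT	TTAGGC		AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC	CAAGCAGAAGACGGCATACGAGATTTAGGCAGATCGGAAGAGCACACGTCTGAACTCCAGTCAC
i4	pcr2_reverse	CAAGCAGAAGACGGCATACGAGAT	TGACCA		AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC	CAAGCAGAAGACGGCATACGAGATTGACCAAGATCGGAAGAGCACACGTCTGAACTCCAGTCAC
i5	pcr2_reverse	CAAGCAGAAGACGGCATACGAGAT	ACAGTG		AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC	CAAGCAGAAGACGGCATACGAGATACAGTGAGATCGGAAGAGCACACGTCTGAACTCCAGTCAC
i6	pcr2_reverse	CAAGCAGAAGACGGCATACGAGAT	GCCAAT		AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC	CAAGCAGAAGACGGCATACGAGATGCCAATAGATCGGAAGAGCACACGTCTGAACTCCAGTCAC
i7	pcr2_reverse	CAAGCAGAAGACGGCATACGAGAT	CAGATC		AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC	CAAGCAGAAGACGGCATACGAGATCAGATCAGATCGGAAGAGCACACGTCTGAACTCCAGTCAC
i8	pcr2_reverse	CAAGCAGAAGACGGCATACGAGAT	ACTTGA		AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC	CAAGCAGAAGACGGCATACGAGATACTTGAAGATCGGAAGAGCACACGTCTGAACTCCAGTCAC
i9	pcr2_reverse	CAAGCAGAAGACGGCATACGAGAT	GATCAG		AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC	CAAGCAGAAGACGGCATACGAGATGATCAGAGATCGGAAGAGCACACGTCTGAACTCCAGTCAC
i10	pcr2_reverse	CAAGCAGAAGACGGCATACGAGAT	TAGCTT		AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC	CAAGCAGAAGACGGCATACGAGATTAGCTTAGATCGGAAGAGCACACGTCTGAACTCCAGTCAC
i11	pcr2_reverse	CAAGCAGAAGACGGCATACGAGAT	GGCTAC		AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC	CAAGCAGAAGACGGCATACGAGATGGCTACAGATCGGAAGAGCACACGTCTGAACTCCAGTCAC
i12	pcr2_reverse	CAAGCAGAAGACGGCATACGAGAT	CTTGTA		AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC	CAAGCAGAAGACGGCATACGAGATCTTGTAAGATCGGAAGAGCACACGTCTGAACTCCAGTCAC
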