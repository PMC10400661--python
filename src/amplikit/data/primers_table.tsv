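# Built-in primer registry: one-step Illumina amplicon oligos for the V4 and
# V1-V2 16S rRNA systems (full oligo = flowcell adaptor + pad + binding region)
# plus the matching custom sequencing/index primers.
# The V1-V2M system is the V1-V2 system with the extra degenerate forward
# primer 68F_M mixed in (rows under region V1-V2M); it shares the V1-V2
# sequencing primers.
# Columns: region	name	conc_umol_per_L	sequence	role
V4	515F	0.2	AATGATACGGCGACCACCGAGATCTACACGCTGCGTAAGATATGGTAATTGTGTGYCAGCMGCCGCGGTAA	forward
V4	806R	0.2	CAAGCAGAAGACGGCATACGAGATTCGCCTTAAGTCAGCCAGCCGGACTACNVGGGTWTCTAAT	reverse
V4	Read1	NA	TATGGTAATTGTGTGCCAGCMGCCGCGGTAA	read1
V4	Read2	NA	AGTCAGTCAGCCGGACTACHVGGGTWTCTAAT	read2
V4	Index1	NA	ATTAGAWACCCBDGTAGTCCGGCTGACTGACT	index1
V4	Index2	NA	TTACCGCGGCKGCTGGCACACAATTACCATA	index2
V1-V2	68F	0.2	AATGATACGGCGACCACCGAGATCTACACGCTCGTCTAATAGTCAGCCAGCCGTNANACATGCAAGTCGRRSG	forward
V1-V2	338R	0.3	CAAGCAGAAGACGGCATACGAGATTCATGAGCTATGGTAATTAAGCTGCCTCCCGTAGGAGT	reverse
V1-V2	Read1	NA	AGTCAGCCAGCCGTNANACATGCAAGTC	read1
V1-V2	Read2	NA	TATGGTAATTAAGCTGCCTCCCGTAGGAGT	read2
V1-V2	Index1	NA	ACTCCTACGGGAGGCAGCTTAATTACCATA	index1
V1-V2	Index2	NA	GACTTGCATGTNTNACGGCTGGCTGACT	index2
V1-V2M	68F_M	0.1	AATGATACGGCGACCACCGAGATCTACACGCTCGTCTAATAGTCAGCCAGCCGTAACACATGCAAGTCRACTYGA	forward
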