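gene	guide	region	n_hits	n_snps	bp_in_loops	at_percent	efficiency	assay	low_efficiency
PVALB	ATTGGGTGTTCAGGGCAGAG	chr22:37196884-37196906(+)	1	1	6	45	6.50%	Surveyor	no
PVALB	GTGGCGAGAGGGGCCGAGAT	chr22:37196866-37196888(+)	1	3	9	30	ND	Surveyor	yes
PVALB	GGGGCCGAGATTGGGTGTTC	chr22:37196875-37196897(+)	1	2	9	35	ND	Surveyor	yes
AAVS1	GGGGCCACTAGGGACAGGAT	chr19:55627117-55627139(-)	1	0	8	35	8.07%	HR	no
AAVS1	GTCCCCTCCACCCCACAGTG	chr19:55627136-55627158(-)	2	0	7	30	3.26%	HR	yes
VEGFA	GGGTGGGGGGAGTTTGCTCC	chr6:43737291-43737313(-)	1	1	11	30	26%	T7EI	yes
VEGFA	GACCCCCTCCACCCCGCCTC	chr6:43738556-43738578(-)	1	0	4	20	50%	T7EI	no
VEGFA	GGTGAGTGAGTGTGTGCGTG	chr6:43737454-43737476(+)	1	0	12	40	49.40%	T7EI	no
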