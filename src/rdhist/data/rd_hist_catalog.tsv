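# Replication-dependent histone gene catalog (72 genes), classic
# HIST* nomenclature (HGNC aliases such as H4C8 for HIST1H4H are the
# user's responsibility to resolve before mapping).
# Cluster convention: HIST1 (chr 6p21-p22), HIST2 (chr 1q21) and HIST3
# (chr 1q42) carry the canonical per-family gene counts of the three
# genomic arrays; replication-dependent histone genes outside those
# enumerations (e.g. the solitary H4 gene HIST4H4 on chr 12, later
# additions to the 1q21 region) are labelled "other".
# The file is plain TSV so it can be audited or replaced wholesale.
gene_symbol	family	cluster
HIST1H1A	H1	HIST1
HIST1H1B	H1	HIST1
HIST1H1C	H1	HIST1
HIST1H1D	H1	HIST1
HIST1H1E	H1	HIST1
HIST1H1T	H1	HIST1
HIST1H2AA	H2A	HIST1
HIST1H2AB	H2A	HIST1
HIST1H2AC	H2A	HIST1
HIST1H2AD	H2A	HIST1
HIST1H2AE	H2A	HIST1
HIST1H2AG	H2A	HIST1
HIST1H2AH	H2A	HIST1
HIST1H2AI	H2A	HIST1
HIST1H2AJ	H2A	HIST1
HIST1H2AK	H2A	HIST1
HIST1H2AL	H2A	HIST1
HIST1H2AM	H2A	HIST1
HIST1H2BA	H2B	HIST1
HIST1H2BB	H2B	HIST1
HIST1H2BC	H2B	HIST1
HIST1H2BD	H2B	HIST1
HIST1H2BE	H2B	HIST1
HIST1H2BF	H2B	HIST1
HIST1H2BG	H2B	HIST1
HIST1H2BH	H2B	HIST1
HIST1H2BI	H2B	HIST1
HIST1H2BJ	H2B	HIST1
HIST1H2BK	H2B	HIST1
HIST1H2BL	H2B	HIST1
HIST1H2BM	H2B	HIST1
HIST1H2BN	H2B	HIST1
HIST1H2BO	H2B	HIST1
HIST1H3A	H3	HIST1
HIST1H3B	H3	HIST1
HIST1H3C	H3	HIST1
HIST1H3D	H3	HIST1
HIST1H3E	H3	HIST1
HIST1H3F	H3	HIST1
HIST1H3G	H3	HIST1
HIST1H3H	H3	HIST1
HIST1H3I	H3	HIST1
HIST1H3J	H3	HIST1
HIST1H4A	H4	HIST1
HIST1H4B	H4	HIST1
HIST1H4C	H4	HIST1
HIST1H4D	H4	HIST1
HIST1H4E	H4	HIST1
HIST1H4F	H4	HIST1
HIST1H4G	H4	HIST1
HIST1H4H	H4	HIST1
HIST1H4I	H4	HIST1
HIST1H4J	H4	HIST1
HIST1H4K	H4	HIST1
HIST1H4L	H4	HIST1
HIST2H2AA3	H2A	HIST2
HIST2H2AB	H2A	HIST2
HIST2H2AC	H2A	HIST2
HIST2H2BE	H2B	HIST2
HIST2H3C	H3	HIST2
HIST2H4A	H4	HIST2
HIST3H2A	H2A	HIST3
HIST3H2BB	H2B	HIST3
HIST3H3	H3	HIST3
HIST4H4	H4	other
HIST2H2AA4	H2A	other
HIST2H2BA	H2B	other
HIST2H2BF	H2B	other
HIST2H3A	H3	other
HIST2H3D	H3	other
HIST2H4B	H4	other
HIST3H2BA	H2B	other
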