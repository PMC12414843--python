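# Synthetic STRING-style edge list over 17 differentially expressed protein
# symbols, constructed as test data: the topology is chosen so that the six
# ECM genes form the densest high-score component; the edges assert nothing
# about real protein-protein associations.
protein1	protein2	combined_score
COL2A1	COL11A1	962
COL2A1	COL6A1	915
COL2A1	COL6A2	908
COL2A1	THBS1	886
COL2A1	LUM	899
COL11A1	COL6A1	941
COL11A1	COL6A2	925
COL11A1	THBS1	872
COL11A1	LUM	903
COL6A1	COL6A2	978
COL6A1	THBS1	890
COL6A1	LUM	884
COL6A2	THBS1	868
COL6A2	LUM	861
THBS1	LUM	857
TUBB3	CLIP1	622
TJP1	TNC	512
CAST	PLIN3	400
MB	PLIN3	399
THBS1	TNC	380
LUM	TNC	352
RPL21	SETD7	214
PZP	MB	183
BCL2L13	CAST	166
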