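# Reference top-ten node rankings of an ovarian endometriosis lncRNA-mRNA
# ceRNA network under three centrality measures. Each column is one ranked
# list (rank 1 = highest centrality).
rank	degree	betweenness	closeness
1	H19	H19	H19
2	GS1-358P8.4	GS1-358P8.4	RECK
3	RP3-523K23.2	RP3-523K23.2	ITGB8
4	AC016747.3	RP11-96D1.10	JAZF1
5	DLX6-AS1	DLX6-AS1	GS1-358P8.4
6	RP11-96D1.10	AC016747.3	DOCK4
7	HOXA-AS2	RP11-284N8.3	CDC42SE2
8	RP11-54O7.1	RP11-379K17.4	TET3
9	HOXA-AS4	HOXA-AS2	TNFAIP3
10	RP11-284N8.3	RP11-54O7.1	PHTF2
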