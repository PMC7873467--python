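# miRNA partners of three endometriosis-associated lncRNAs (curated
# reference interactions; target_class is lncRNA for every row).
mirna_id	target_id	target_class
miR-106a-5p	H19	lncRNA
miR-106b-5p	H19	lncRNA
miR-107	H19	lncRNA
miR-130b-3p	H19	lncRNA
miR-138-5p	H19	lncRNA
miR-17-5p	H19	lncRNA
miR-18a-5p	H19	lncRNA
miR-18b-5p	H19	lncRNA
miR-196b-5p	H19	lncRNA
miR-19a-3p	H19	lncRNA
miR-19b-3p	H19	lncRNA
miR-20a-5p	H19	lncRNA
miR-20b-5p	H19	lncRNA
miR-216b-5p	H19	lncRNA
miR-29c-3p	H19	lncRNA
miR-301a-3p	H19	lncRNA
miR-599	H19	lncRNA
miR-93-5p	H19	lncRNA
miR-106a-5p	GS1-358P8.4	lncRNA
miR-106b-5p	GS1-358P8.4	lncRNA
miR-107	GS1-358P8.4	lncRNA
miR-17-5p	GS1-358P8.4	lncRNA
miR-18a-5p	GS1-358P8.4	lncRNA
miR-18b-5p	GS1-358P8.4	lncRNA
miR-190b	GS1-358P8.4	lncRNA
miR-196b-5p	GS1-358P8.4	lncRNA
miR-20a-5p	GS1-358P8.4	lncRNA
miR-20b-5p	GS1-358P8.4	lncRNA
miR-216a-5p	GS1-358P8.4	lncRNA
miR-372-3p	GS1-358P8.4	lncRNA
miR-382-5p	GS1-358P8.4	lncRNA
miR-497-5p	GS1-358P8.4	lncRNA
miR-542-3p	GS1-358P8.4	lncRNA
miR-93-5p	GS1-358P8.4	lncRNA
miR-199b-5p	RP11-96D1.10	lncRNA
miR-202-3p	RP11-96D1.10	lncRNA
miR-222-3p	RP11-96D1.10	lncRNA
miR-497-5p	RP11-96D1.10	lncRNA
miR-9-5p	RP11-96D1.10	lncRNA
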