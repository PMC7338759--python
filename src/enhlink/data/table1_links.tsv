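# Published table of 26 enhancer-miRNA links with evidence flags
# (distance / TAD / chromatin contact). Coordinates are 1-based inclusive
# as printed and are converted to 0-based half-open on load (start - 1).
# The comment column flags rows whose check-mark-to-column alignment was
# typographically ambiguous in the source; "." means unambiguous.
enhancer_chrom	enhancer_start	enhancer_end	target_id	target_type	log2fc	evidence_distance	evidence_tad	evidence_contact	comment
chr1	161612422	161612716	hsa-miR-4654	miRNA	2.20	0	1	0	.
chr1	161612422	161612716	hsa-miR-556-5p	miRNA	3.95	0	1	0	.
chr2	239632126	239646548	hsa-miR-2467-5p	miRNA	9.73	1	1	0	.
chr2	239632126	239646548	hsa-miR-4786-5p	miRNA	7.43	0	1	0	.
chr7	128236919	128237387	hsa-miR-129-5p	miRNA	3.77	0	1	0	.
chr7	130373756	130374065	hsa-miR-335-3p	miRNA	7.71	0	1	0	.
chr7	130373756	130374065	hsa-miR-29a-3p	miRNA	-4.01	0	0	1	.
chr7	130373756	130374065	hsa-miR-29b-3p	miRNA	-4.02	0	0	1	.
chr7	130896838	130897634	hsa-miR-29a-3p	miRNA	-4.01	0	1	0	.
chr7	130896838	130897634	hsa-miR-29b-3p	miRNA	-4.02	0	1	0	.
chr7	135300381	135315387	hsa-miR-6509-5p	miRNA	5.11	1	1	0	.
chr8	95220062	95224485	hsa-miR-3150a-3p	miRNA	3.75	0	1	0	.
chr8	95220062	95224485	hsa-miR-3150a-5p	miRNA	5.29	0	1	0	.
chr11	66970815	66971421	hsa-miR-3163	miRNA	3.75	0	1	1	.
chr11	118912202	118912669	hsa-miR-6716-3p	miRNA	6.10	0	1	0	.
chr13	50529144	50529602	hsa-miR-16-5p	miRNA	3.12	1	1	0	.
chr13	50529144	50529602	hsa-miR-3613-5p	miRNA	5.21	1	1	0	.
chr14	95265396	95265951	hsa-miR-3173-5p	miRNA	3.04	0	1	0	.
chr14	104348582	104353696	hsa-miR-203a-3p	miRNA	4.72	1	1	0	.
chr16	57893719	57894288	hsa-miR-6772-3p	miRNA	6.11	0	1	1	.
chr17	56915657	56916183	hsa-miR-3614-5p	miRNA	5.22	1	1	0	.
chr17	57187353	57253506	hsa-miR-3614-5p	miRNA	5.22	0	1	0	.
chr19	782330	783005	hsa-miR-4745-5p	miRNA	4.65	1	1	1	.
chr20	62651854	62652518	hsa-miR-4758-3p	miRNA	4.95	0	1	0	.
chr22	37898835	37899016	hsa-miR-659-5p	miRNA	4.14	0	1	0	.
chr22	37898835	37899016	hsa-miR-6820-5p	miRNA	3.70	0	1	0	.
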