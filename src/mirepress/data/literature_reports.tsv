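mirna_id	reports
hsa-miR-17*	up,up,up
hsa-miR-16-2*	NULL
hsa-miR-30c-2*	NULL
hsa-miR-574-3p	down
hsa-miR-592	NULL
hsa-miR-630	up
hsa-miR-17	up,down
hsa-miR-19b	up,up
hsa-miR-21	up,up
hsa-miR-22	down
hsa-miR-20a	up,up,up,up
hsa-miR-92a	up
hsa-miR-29b	up
hsa-miR-192	down,down
hsa-miR-7	up
hsa-miR-10b	down,down
hsa-miR-215	down,up
hsa-miR-224	up,up,up,up
hsa-miR-150	up
hsa-miR-194	up
hsa-miR-20b	down
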