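# Published per-drug study-type counts for an ACE-inhibitor PubMed corpus.
# distinct_records: 23294
drug	in_vitro	in_vivo	clinical	total
enalapril	1733	4177	4725	10635
captopril	2405	5438	1742	9585
benazepril	737	1297	2057	4091
ramipril	357	792	746	1895
lisinopril	408	719	758	1885
perindopril	248	589	675	1512
enalaprilat	410	771	168	1349
quinapril	121	284	245	650
trandolapril	68	162	253	483
cilazapril	77	200	197	474
fosinopril	89	170	175	434
imidapril	52	142	61	255
temocapril	51	94	32	177
zofenopril	48	73	45	166
racecadotril	33	85	43	161
delapril	20	58	44	122
spirapril	10	35	63	108
moexipril	14	26	32	72
alacepril	20	38	11	69
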