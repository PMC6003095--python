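sag_name	taxonomy	depth_m	n50	assembly_size	completeness
Opi.OSU.00C	Opitutae	250	16460	2077522	0.78
E01.OSU.003	E01-9C-26 marine group	250	4189	3328816	0.66
E01.OSU.005	E01-9C-26 marine group	250	5014	2696361	0.54
Acd.OSU.001	Sva0996 marine group	250	2517	1422628	0.48
E01.OSU.004	E01-9C-26 marine group	250	3896	1851821	0.39
Nsp.OSU.006	Nitrospina	250	1981	1282535	0.27
S16.OSU.00H	SAR116 clade	20	3512	789214	0.27
Arc.OSU.008	Arctic97B-4 marine group	250	5470	1518022	0.13
Agn.OSU.007	AEGEAN_245	250	7532	246227	0.10
Pro.OSU.00F	Prochlorococcus	20	631	72564	0.06
Nsp.OSU.00B	Nitrospina	250	5581	639460	0.05
Pln.OSU.00D	Planctomyces	250	1643	797959	0.04
Syn.OSU.00J	Synechococcus	20	786	164756	0.04
E01.OSU.002	E01-9C-26 marine group	250	549	440564	0.02
Kte.OSU.009	Ktedonobacterales	20	461	6202	0.00
Met.OSU.00A	Methylobacterium	250	7531	289220	0.00
Rho.OSU.00G	Rhodobacteraceae, uncultured	20	850	6009	0.00
Sph.OSU.00I	Sphingomonas	20	745	12452	0.00
Syn.OSU.00K	Synechococcus	20	828	100639	0.00
Syn.OSU.00L	Synechococcus	20	1393	39437	0.00
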